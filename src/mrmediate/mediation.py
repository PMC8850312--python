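"""Counterfactual mediation for a survival outcome.

Two models carry the decomposition: a linear (OLS) mediator model
M = b0 + b1*A + b2'C + eps and a Cox outcome model whose log hazard is
linear in exposure A, mediator M and covariates C with *no* A x M
interaction.  Under the rare-outcome approximation the natural effects for
an exposure contrast delta_a = a - a* on the log-hazard-ratio scale are

    NDE = theta1 * delta_a
    NIE = theta2 * b1 * delta_a
    TE  = NDE + NIE          (exactly, by construction)
    proportion mediated = NIE / TE

with theta1, theta2 the Cox coefficients of exposure and mediator.
Delta-method variances treat the two fitted models as independent;
a subject-resampling bootstrap provides percentile CIs as the
publication-grade alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_models import MODEL2_COVARIATES, CoxFit, fit_cox
from .errors import ConvergenceError, InputError
from .summary_io import SummaryTable  # noqa: F401  (re-export convenience)

logger = logging.getLogger(__name__)

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MediatorFit:
    """OLS fit of the mediator on exposure + covariates."""

    params: pd.Series  # const, exposure, covariates
    cov: pd.DataFrame
    sigma: float  # residual SD
    exposure: str
    n_used: int

    @property
    def beta1(self) -> float:
        return float(self.params[self.exposure])

    @property
    def var_beta1(self) -> float:
        return float(self.cov.loc[self.exposure, self.exposure])


@dataclass
class MediationResult:
    nde_log: float
    nie_log: float
    te_log: float
    proportion_mediated: float
    delta_a: float
    method: str  # delta | bootstrap
    se_nde: float
    se_nie: float
    se_te: float
    nde_ci: tuple[float, float]  # HR scale
    nie_ci: tuple[float, float]
    te_ci: tuple[float, float]
    pm_ci: tuple[float, float] | None = None
    pval_nde: float | None = None
    pval_nie: float | None = None

    @property
    def nde_hr(self) -> float:
        return float(np.exp(self.nde_log))

    @property
    def nie_hr(self) -> float:
        return float(np.exp(self.nie_log))

    @property
    def te_hr(self) -> float:
        return float(np.exp(self.te_log))


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the preceding ones (QR-style sweep)."""
    bad, kept = [], []
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        cand = arr[:, kept + [j]] if kept else arr[:, [j]]
        if np.linalg.matrix_rank(cand) <= len(kept):
            bad.append(name)
        else:
            kept.append(j)
    return bad


def fit_mediator_model(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: list[str] | None = None,
) -> MediatorFit:
    """Ordinary least squares of the mediator on exposure + covariates
    (complete cases)."""
    covariates = list(covariates or [])
    cols = [mediator, exposure] + covariates
    cc = data[cols].dropna()
    n_params = len(covariates) + 2
    if len(cc) < n_params + 2:
        raise InputError(
            f"need >= {n_params + 2} complete cases, got {len(cc)}"
        )
    X = sm.add_constant(cc[[exposure] + covariates], has_constant="add")
    bad = _find_collinear(X)
    if bad:
        raise InputError(f"collinear design; offending columns: {bad}")
    res = sm.OLS(cc[mediator], X).fit()
    return MediatorFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index,
                         columns=res.params.index),
        sigma=float(np.sqrt(res.scale)),
        exposure=exposure,
        n_used=int(res.nobs),
    )


def mediation_effects(
    mediator_fit: MediatorFit,
    outcome_fit: CoxFit,
    delta_a: float,
    exposure: str,
    mediator: str,
) -> MediationResult:
    """Natural direct/indirect effect decomposition on the log-HR scale with
    delta-method CIs.

    Requires a Cox outcome fit containing both the exposure and the mediator
    term and no exposure x mediator interaction; valid in the rare-outcome
    regime.
    """
    for term in (exposure, mediator):
        if term not in outcome_fit.params.index:
            raise InputError(f"outcome model lacks the '{term}' term")
    theta1 = float(outcome_fit.params[exposure])
    theta2 = float(outcome_fit.params[mediator])
    var_t1 = float(outcome_fit.cov.loc[exposure, exposure])
    var_t2 = float(outcome_fit.cov.loc[mediator, mediator])
    cov_t12 = float(outcome_fit.cov.loc[exposure, mediator])
    b1 = mediator_fit.beta1
    var_b1 = mediator_fit.var_beta1

    nde = theta1 * delta_a
    nie = theta2 * b1 * delta_a
    te = nde + nie
    var_nde = delta_a**2 * var_t1
    var_nie = delta_a**2 * (b1**2 * var_t2 + theta2**2 * var_b1)
    # TE variance keeps the within-Cox covariance of theta1 and theta2
    var_te = var_nde + var_nie + 2 * delta_a**2 * b1 * cov_t12

    if te == 0:
        pm = np.nan
        logger.warning("total effect is exactly zero; proportion mediated undefined")
    else:
        pm = nie / te
        if not (0.0 <= pm <= 1.0):
            logger.warning(
                "opposite-signed direct and indirect effects: proportion "
                "mediated %.3f outside [0, 1]", pm,
            )

    se_nde, se_nie, se_te = np.sqrt([var_nde, var_nie, max(var_te, 0.0)])
    return MediationResult(
        nde_log=nde,
        nie_log=nie,
        te_log=te,
        proportion_mediated=float(pm),
        delta_a=float(delta_a),
        method="delta",
        se_nde=float(se_nde),
        se_nie=float(se_nie),
        se_te=float(se_te),
        nde_ci=(float(np.exp(nde - _Z95 * se_nde)), float(np.exp(nde + _Z95 * se_nde))),
        nie_ci=(float(np.exp(nie - _Z95 * se_nie)), float(np.exp(nie + _Z95 * se_nie))),
        te_ci=(float(np.exp(te - _Z95 * se_te)), float(np.exp(te + _Z95 * se_te))),
        pval_nde=float(2 * stats.norm.sf(abs(nde / se_nde))) if se_nde > 0 else None,
        pval_nie=float(2 * stats.norm.sf(abs(nie / se_nie))) if se_nie > 0 else None,
    )


def mediate(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "event",
    delta_a: float | str = "sd",
    ties: str = "efron",
    on_separation: str = "raise",
) -> tuple[MediationResult, MediatorFit, CoxFit]:
    """Fit both models on complete cases and decompose the exposure effect.

    ``delta_a='sd'`` contrasts one sample standard deviation of the exposure
    (the reference level a* is immaterial under the no-interaction
    linear/Cox specification — only the difference enters).
    """
    covariates = list(MODEL2_COVARIATES) if covariates is None else list(covariates)
    if isinstance(delta_a, str):
        if delta_a != "sd":
            raise InputError(f"delta_a must be a float or 'sd', got {delta_a!r}")
        delta_a = float(data[exposure].dropna().std(ddof=1))
    med_fit = fit_mediator_model(data, exposure, mediator, covariates)
    out_fit = fit_cox(
        data, [exposure, mediator] + covariates, duration_col, event_col,
        ties=ties, on_separation=on_separation,
    )
    result = mediation_effects(med_fit, out_fit, delta_a, exposure, mediator)
    return result, med_fit, out_fit


def mediation_bootstrap(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "event",
    delta_a: float | str = "sd",
    n_boot: int = 500,
    seed: int | None = None,
    ties: str = "efron",
) -> MediationResult:
    """Subject-resampling bootstrap: percentile 95% CIs for NDE, NIE, TE and
    the proportion mediated; point estimates stay at the full-data values.

    Replicates that fail to converge are skipped; more than 10% failures is
    an error.
    """
    if n_boot < 200:
        raise InputError(f"n_boot must be >= 200, got {n_boot}")
    point, _, _ = mediate(
        data, exposure, mediator, covariates, duration_col, event_col, delta_a, ties
    )
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = {"nde": [], "nie": [], "te": [], "pm": []}
    n_fail = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            # a diverged rare-covariate nuisance term in a replicate is
            # harmless for the effect terms: warn instead of failing
            res, _, _ = mediate(
                boot, exposure, mediator, covariates, duration_col, event_col,
                point.delta_a, ties, on_separation="warn",
            )
        except (ConvergenceError, InputError):
            n_fail += 1
            continue
        draws["nde"].append(res.nde_log)
        draws["nie"].append(res.nie_log)
        draws["te"].append(res.te_log)
        draws["pm"].append(res.proportion_mediated)
    if n_fail > 0.1 * n_boot:
        raise ConvergenceError(
            f"{n_fail}/{n_boot} bootstrap replicates failed to converge"
        )

    def ci(key, transform=np.exp):
        lo, hi = np.percentile(draws[key], [2.5, 97.5])
        return (float(transform(lo)), float(transform(hi)))

    return MediationResult(
        nde_log=point.nde_log,
        nie_log=point.nie_log,
        te_log=point.te_log,
        proportion_mediated=point.proportion_mediated,
        delta_a=point.delta_a,
        method="bootstrap",
        se_nde=float(np.std(draws["nde"], ddof=1)),
        se_nie=float(np.std(draws["nie"], ddof=1)),
        se_te=float(np.std(draws["te"], ddof=1)),
        nde_ci=ci("nde"),
        nie_ci=ci("nie"),
        te_ci=ci("te"),
        pm_ci=ci("pm", transform=lambda x: x),
        pval_nde=point.pval_nde,
        pval_nie=point.pval_nie,
    )
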