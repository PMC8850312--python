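"""Cohort construction and Cox proportional-hazards modelling.

Follow-up runs from enrollment to the earliest of diagnosis, death, loss to
follow-up, or the administrative end of follow-up; only a diagnosis counts
as an event.  Hazard ratios are estimated by maximizing the Cox partial
likelihood with the Efron approximation for tied event times (Breslow
available for cross-checks) via damped Newton iterations with step-halving.
Exposures are analysed continuous per sample standard deviation, binary at a
clinical threshold, or in quartiles with the lowest quartile as reference;
three nested covariate-adjustment sets mirror a typical epidemiological
model-1/2/3 progression.  The proportional-hazards assumption is assessed by
correlating scaled Schoenfeld residuals with follow-up time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, InputError

YEAR_DAYS = 365.25
_Z95 = float(stats.norm.ppf(0.975))

#: Nested adjustment sets (model 3 additionally adjusts for the co-exposure).
MODEL1_COVARIATES = ["age", "smoking", "drinking", "education", "marital", "batch"]
MODEL2_COVARIATES = MODEL1_COVARIATES + [
    "parity", "menopause_age", "mastitis", "diuretics", "antibiotics", "hrt",
]


@dataclass(frozen=True)
class CoxModelSpec:
    """Which exposure, which adjustment set, which exposure coding."""

    exposure: str
    model: int = 3  # 1, 2 or 3
    coding: str = "sd"  # sd | binary | quartile
    co_adjust: str | None = None  # the other exposure, added in model 3
    binary_threshold: float = 24.0
    ties: str = "efron"

    def covariates(self) -> list[str]:
        if self.model == 1:
            base = list(MODEL1_COVARIATES)
        elif self.model == 2:
            base = list(MODEL2_COVARIATES)
        elif self.model == 3:
            base = list(MODEL2_COVARIATES)
            if self.co_adjust:
                base.append(self.co_adjust)
        else:
            raise InputError(f"model must be 1, 2 or 3, got {self.model}")
        return base


@dataclass
class QuartileAssignment:
    cut_points: tuple[float, float, float]
    labels: pd.Series  # 'Q1'..'Q4', NaN preserved


@dataclass
class CoxFit:
    """Maximum-partial-likelihood fit.

    ``params`` are log hazard ratios; ``cov`` is the inverse observed
    information.  ``summary()`` reports HR = exp(coef) with normal 95% CIs
    exp(coef +/- 1.96 se).
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_used: int
    n_events: int
    ties: str
    n_iter: int
    score_norm: float

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "hr": np.exp(self.params),
                "ci_low": np.exp(self.params - _Z95 * se),
                "ci_high": np.exp(self.params + _Z95 * se),
                "pval": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    # alias used in reporting code
    def hazard_ratios(self) -> pd.DataFrame:
        return self.summary()[["hr", "ci_low", "ci_high", "pval"]]


# ---------------------------------------------------------------------------
# follow-up construction


def compute_follow_up(
    enroll_date,
    admin_end_date,
    diagnosis_date=None,
    death_date=None,
    loss_date=None,
) -> tuple[float, bool]:
    """Follow-up time in years (days/365.25) and event indicator.

    The clock stops at the earliest of diagnosis, death, loss to follow-up
    and the administrative end; the event flag is true only when that
    earliest date is a diagnosis (a diagnosis tied with another date counts
    as an event).
    """
    enroll = pd.Timestamp(enroll_date)
    if pd.isna(enroll):
        raise InputError("enrollment date is required")
    candidates = {"admin": pd.Timestamp(admin_end_date)}
    for name, d in (("diagnosis", diagnosis_date), ("death", death_date), ("loss", loss_date)):
        if d is not None and not pd.isna(pd.Timestamp(d)):
            candidates[name] = pd.Timestamp(d)
    end = min(candidates.values())
    if end < enroll:
        raise InputError(f"follow-up end {end.date()} precedes enrollment {enroll.date()}")
    time_years = (end - enroll).days / YEAR_DAYS
    event = candidates.get("diagnosis") == end
    return time_years, bool(event)


def sensitivity_exclude_first_year(
    data: pd.DataFrame, duration_col: str = "time_years", event_col: str = "event"
) -> pd.DataFrame:
    """Drop subjects *diagnosed* within the first year of follow-up; subjects
    censored before one year are kept."""
    early_case = (data[event_col].astype(bool)) & (data[duration_col] < 1.0)
    return data.loc[~early_case].copy()


# ---------------------------------------------------------------------------
# exposure coding


def per_sd(values) -> tuple[pd.Series, float]:
    """Divide by the complete-case sample SD (denominator n-1); missing
    values propagate."""
    s = pd.Series(values, dtype=float)
    complete = s.dropna()
    if len(complete) < 2:
        raise InputError("per_sd needs >= 2 non-missing values")
    sd = float(complete.std(ddof=1))
    if sd == 0:
        raise InputError("per_sd: zero variance")
    return s / sd, sd


def assign_quartiles(values) -> QuartileAssignment:
    """Quartile groups from the empirical 25/50/75th percentiles
    (linear-interpolation definition); a value tied with a boundary goes to
    the lower group."""
    s = pd.Series(values, dtype=float)
    complete = s.dropna()
    if len(complete) < 4:
        raise InputError("assign_quartiles needs >= 4 non-missing values")
    if complete.nunique() == 1:
        raise InputError("assign_quartiles: all values equal")
    q1, q2, q3 = np.percentile(complete, [25, 50, 75], method="linear")
    labels = pd.Series(index=s.index, dtype=object)
    labels[s <= q1] = "Q1"
    labels[(s > q1) & (s <= q2)] = "Q2"
    labels[(s > q2) & (s <= q3)] = "Q3"
    labels[s > q3] = "Q4"
    labels[s.isna()] = np.nan
    return QuartileAssignment(cut_points=(float(q1), float(q2), float(q3)), labels=labels)


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _cox_quantities(X, t, e, beta, ties: str):
    """Log partial likelihood, score and observed information at ``beta``.

    Arrays must be pre-sorted by ascending time.  Efron's correction
    down-weights tied event subjects within their own risk-set denominator;
    with ``ties='breslow'`` the correction term is dropped.
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    eta = eta - eta.max()  # partial likelihood invariant to a constant shift
    w = np.exp(eta)
    efron = ties == "efron"

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))

    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and t[j] == t[i]:
            j -= 1
        sl = slice(j + 1, i + 1)  # all subjects with this time enter the risk set
        Xg, wg, eg = X[sl], w[sl], e[sl]
        S0 += wg.sum()
        if p:
            S1 += wg @ Xg
            S2 += (Xg * wg[:, None]).T @ Xg
        d = int(eg.sum())
        if d:
            frac = (np.arange(d) / d) if efron else np.zeros(d)
            wD = wg[eg]
            sd0 = wD.sum()
            denom = S0 - frac * sd0
            loglik += eta[sl][eg].sum() - np.log(denom).sum()
            if p:
                XD = Xg[eg]
                sd1 = wD @ XD
                sd2 = (XD * wD[:, None]).T @ XD
                mean1 = (S1[None, :] - frac[:, None] * sd1) / denom[:, None]
                mean2 = (S2[None, :, :] - frac[:, None, None] * sd2) / denom[:, None, None]
                score += XD.sum(axis=0) - mean1.sum(axis=0)
                info += mean2.sum(axis=0) - np.einsum("lp,lq->pq", mean1, mean1)
        i = j
    return loglik, score, info


def fit_cox(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_years",
    event_col: str = "event",
    ties: str = "efron",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
    on_separation: str = "raise",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by damped Newton iterations.

    Complete-case analysis: rows missing the duration, event indicator or
    any covariate are dropped.  Steps that would decrease the partial
    likelihood are halved; convergence requires max |score| < ``score_tol``
    or a relative log-likelihood change below ``loglik_tol``.

    A term whose likelihood is monotone (separation: e.g. a rare binary
    covariate with no events in one group) is flagged; ``on_separation``
    chooses between raising a :class:`ConvergenceError` ('raise', default)
    and logging a warning while returning the fit ('warn', useful inside
    bootstrap replicates where a diverged nuisance term is harmless).
    """
    if ties not in ("efron", "breslow"):
        raise InputError(f"ties must be 'efron' or 'breslow', got {ties}")
    if on_separation not in ("raise", "warn"):
        raise InputError(f"on_separation must be 'raise' or 'warn', got {on_separation}")
    cols = [duration_col, event_col] + list(covariates)
    cc = data[cols].dropna()
    n = len(cc)
    t = cc[duration_col].to_numpy(dtype=float)
    e = cc[event_col].to_numpy(dtype=bool)
    n_events = int(e.sum())
    if n_events < 1:
        raise InputError("no events among complete cases")
    if np.any(t < 0):
        raise InputError("negative follow-up times")

    X = cc[list(covariates)].to_numpy(dtype=float)
    p = X.shape[1]
    center = X.mean(axis=0) if p else np.zeros(0)
    Xc = X - center  # centering leaves coefficients and likelihood unchanged

    order = np.argsort(t, kind="stable")
    Xs, ts, es = Xc[order], t[order], e[order]

    beta = np.zeros(p)
    loglik, score, info = _cox_quantities(Xs, ts, es, beta, ties)
    n_iter = 0
    if p:
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                raise ConvergenceError(
                    "singular information matrix (collinear covariates?)",
                    {"iteration": n_iter, "beta": beta},
                ) from None
            size = 1.0
            for _ in range(40):
                cand = beta + size * step
                ll_new, sc_new, info_new = _cox_quantities(Xs, ts, es, cand, ties)
                if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                    break
                size /= 2
            else:
                raise ConvergenceError(
                    "step-halving failed to improve the partial likelihood",
                    {"iteration": n_iter, "beta": beta, "loglik": loglik},
                )
            rel_change = abs(ll_new - loglik) / (abs(loglik) + 1e-12)
            beta, score, info = cand, sc_new, info_new
            prev_loglik, loglik = loglik, ll_new
            if np.max(np.abs(beta)) > 200:
                raise ConvergenceError(
                    "coefficients diverging; monotone likelihood (separation) suspected",
                    {"iteration": n_iter, "beta": beta},
                )
            if np.max(np.abs(score)) < score_tol or rel_change < loglik_tol:
                break
        else:
            raise ConvergenceError(
                f"no convergence after {max_iter} iterations",
                {"score_norm": float(np.max(np.abs(score))), "loglik": loglik},
            )
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information at the optimum") from None
        # monotone likelihood leaves a vanishing score at a diverging beta;
        # it shows up as an absurd SE on the standardized covariate scale
        sd_x = Xc.std(axis=0, ddof=1)
        se_std = np.sqrt(np.diag(cov)) * np.where(sd_x > 0, sd_x, 1.0)
        if np.any(se_std > 50):
            bad = [c for c, flag in zip(covariates, se_std > 50) if flag]
            if on_separation == "raise":
                raise ConvergenceError(
                    "monotone likelihood (separation) suspected", {"terms": bad}
                )
            logging.getLogger(__name__).warning(
                "monotone likelihood (separation) suspected for %s; "
                "returning the fit anyway", bad,
            )
    else:
        cov = np.zeros((0, 0))

    idx = pd.Index(list(covariates))
    return CoxFit(
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        loglik=float(loglik),
        n_used=n,
        n_events=n_events,
        ties=ties,
        n_iter=n_iter,
        score_norm=float(np.max(np.abs(score))) if p else 0.0,
    )


def ph_check(
    fit: CoxFit,
    data: pd.DataFrame,
    duration_col: str = "time_years",
    event_col: str = "event",
) -> pd.Series:
    """Proportional-hazards check: per-term p-value for the Pearson
    correlation of scaled Schoenfeld residuals with follow-up time.

    Residuals at each event are the subject's covariates minus the
    risk-set average under the fitted coefficients; scaling follows the
    Grambsch–Therneau convention d * V_hat * s_i.  Terms with p < 0.05
    indicate a hazard ratio drifting with time.
    """
    terms = list(fit.params.index)
    if not terms:
        return pd.Series(dtype=float)
    cols = [duration_col, event_col] + terms
    cc = data[cols].dropna()
    t = cc[duration_col].to_numpy(dtype=float)
    e = cc[event_col].to_numpy(dtype=bool)
    X = cc[terms].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]

    beta = fit.params.to_numpy()
    eta = X @ beta
    eta -= eta.max()
    w = np.exp(eta)
    # reverse-cumulative risk-set sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    # first index of each tied-time block, so ties share one risk set
    first = np.searchsorted(t, t, side="left")
    means = S1[first] / S0[first, None]
    resid = (X - means)[e]
    scaled = fit.n_events * resid @ fit.cov.to_numpy()
    t_event = t[e]

    pvals = {}
    for k, name in enumerate(terms):
        col = scaled[:, k]
        if np.std(col) == 0 or np.std(t_event) == 0:
            pvals[name] = np.nan
        else:
            pvals[name] = stats.pearsonr(col, t_event).pvalue
    return pd.Series(pvals, name="ph_pval")


# ---------------------------------------------------------------------------
# model suite


def run_model_suite(
    data: pd.DataFrame,
    exposure: str = "bmi",
    mediator: str = "ua",
    duration_col: str = "time_years",
    event_col: str = "event",
    models: tuple[int, ...] = (1, 2, 3),
    binary_threshold: float = 24.0,
    ties: str = "efron",
) -> pd.DataFrame:
    """Fit the nested covariate models for the exposure (continuous per-SD
    and binary at ``binary_threshold``) and the mediator (continuous per-SD
    and quartiles, lowest quartile as reference); returns a tidy table with
    person-years and events per stratum and HR/CI/p per term."""
    df = data.copy()
    exp_sd_col, med_sd_col = f"{exposure}_per_sd", f"{mediator}_per_sd"
    df[exp_sd_col], _ = per_sd(df[exposure])
    df[med_sd_col], _ = per_sd(df[mediator])
    df[f"{exposure}_high"] = (df[exposure] >= binary_threshold).astype(float)
    df.loc[df[exposure].isna(), f"{exposure}_high"] = np.nan
    quart = assign_quartiles(df[mediator])
    for q in ("Q2", "Q3", "Q4"):
        df[f"{mediator}_{q}"] = (quart.labels == q).astype(float)
        df.loc[quart.labels.isna(), f"{mediator}_{q}"] = np.nan

    rows = []

    def _strata(var_col, labels_by_row):
        """Person-years and events per stratum among rows complete for var."""
        ok = df[var_col].notna() & df[duration_col].notna() & df[event_col].notna()
        out = {}
        for lab in labels_by_row[ok].unique():
            m = ok & (labels_by_row == lab)
            out[lab] = (float(df.loc[m, duration_col].sum()), int(df.loc[m, event_col].sum()))
        return out

    def _fit(term_cols, model, extra_adjust):
        covs = CoxModelSpec(exposure=exposure, model=model, co_adjust=extra_adjust).covariates()
        fit = fit_cox(df, term_cols + covs, duration_col, event_col, ties=ties)
        return fit

    binary_labels = pd.Series(
        np.where(df[f"{exposure}_high"] == 1, f">={binary_threshold}", f"<{binary_threshold}"),
        index=df.index, dtype=object,
    )
    binary_labels[df[f"{exposure}_high"].isna()] = np.nan
    exp_strata = _strata(f"{exposure}_high", binary_labels)
    quart_strata = _strata(f"{mediator}_Q2", quart.labels)

    for model in models:
        # exposure per SD, adjusted for mediator per SD in model 3
        fit = _fit([exp_sd_col], model, med_sd_col if model == 3 else None)
        py = float(df.loc[df[exp_sd_col].notna(), duration_col].sum())
        ev = int(df.loc[df[exp_sd_col].notna(), event_col].sum())
        s = fit.summary().loc[exp_sd_col]
        rows.append((exposure, "per_sd", "per SD", model, py, ev,
                     s.hr, s.ci_low, s.ci_high, s.pval))
        # exposure binary
        fit = _fit([f"{exposure}_high"], model, med_sd_col if model == 3 else None)
        lo, hi = f"<{binary_threshold}", f">={binary_threshold}"
        py0, ev0 = exp_strata.get(lo, (np.nan, 0))
        rows.append((exposure, "binary", lo, model, py0, ev0, 1.0, np.nan, np.nan, np.nan))
        s = fit.summary().loc[f"{exposure}_high"]
        py1, ev1 = exp_strata.get(hi, (np.nan, 0))
        rows.append((exposure, "binary", hi, model, py1, ev1,
                     s.hr, s.ci_low, s.ci_high, s.pval))
        # mediator per SD, adjusted for exposure per SD in model 3
        fit = _fit([med_sd_col], model, exp_sd_col if model == 3 else None)
        py = float(df.loc[df[med_sd_col].notna(), duration_col].sum())
        ev = int(df.loc[df[med_sd_col].notna(), event_col].sum())
        s = fit.summary().loc[med_sd_col]
        rows.append((mediator, "per_sd", "per SD", model, py, ev,
                     s.hr, s.ci_low, s.ci_high, s.pval))
        # mediator quartiles
        qcols = [f"{mediator}_{q}" for q in ("Q2", "Q3", "Q4")]
        fit = _fit(qcols, model, exp_sd_col if model == 3 else None)
        pyq, evq = quart_strata.get("Q1", (np.nan, 0))
        rows.append((mediator, "quartile", "Q1", model, pyq, evq, 1.0, np.nan, np.nan, np.nan))
        for q in ("Q2", "Q3", "Q4"):
            s = fit.summary().loc[f"{mediator}_{q}"]
            pyq, evq = quart_strata.get(q, (np.nan, 0))
            rows.append((mediator, "quartile", q, model, pyq, evq,
                         s.hr, s.ci_low, s.ci_high, s.pval))

    return pd.DataFrame(
        rows,
        columns=["variable", "coding", "stratum", "model", "person_years",
                 "n_events", "hr", "ci_low", "ci_high", "pval"],
    )
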