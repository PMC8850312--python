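"""Two-sample Mendelian randomization estimators.

Given harmonized per-variant effects (beta_X, se_X) on the exposure and
(beta_Y, se_Y) on the outcome, each variant j yields a Wald-ratio estimate
beta_Yj / beta_Xj of the causal effect.  The estimators here combine those
ratios under progressively weaker assumptions:

* fixed-effect inverse-variance weighting (IVW) — all instruments valid,
  one common causal effect; algebraically the weighted least-squares slope
  of beta_Y on beta_X through the origin with weights 1/se_Y^2;
* the weighted median — consistent when instruments carrying at least half
  of the total weight are valid; bootstrap standard error;
* an outlier-resampling procedure (MR-PRESSO style) — compares the observed
  weighted residual sum of squares of the beta_Y ~ beta_X regression against
  its simulated null distribution, flags per-variant outliers, and reports
  an IVW estimate on the non-outliers.

A bidirectional driver runs instrument selection plus all three estimators
in both causal directions, with and without a pleiotropy exclusion list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InputError
from .iv_selection import SelectionConfig, select_instruments
from .summary_io import SummaryTable

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with first-order (delta-method) SE."""

    snp_id: str
    ratio: float
    se_ratio: float


@dataclass(frozen=True)
class MrEstimate:
    method: str  # IVW | weighted_median | MR_PRESSO
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int


@dataclass
class PressoResult:
    global_pval: float
    outlier_pvals: pd.Series  # Bonferroni-adjusted, indexed by snp_id
    outlier_ids: list[str]
    corrected: MrEstimate
    rss_obs: float
    n_simulations: int
    seed: int | None


def wald_ratio(snp) -> RatioEstimate:
    """Single-instrument causal estimate beta_Y/beta_X with SE se_Y/|beta_X|."""
    if snp.beta_exposure == 0:
        raise InputError(f"{snp.snp_id}: zero exposure beta, degenerate instrument")
    return RatioEstimate(
        snp_id=snp.snp_id,
        ratio=snp.beta_outcome / snp.beta_exposure,
        se_ratio=snp.se_outcome / abs(snp.beta_exposure),
    )


def _arrays(table: SummaryTable):
    df = table.df
    if len(df) == 0:
        raise InputError("empty summary table")
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    if np.any(bx == 0):
        bad = df.loc[bx == 0, "snp_id"].tolist()
        raise InputError(f"zero exposure beta for {bad}")
    return bx, by, sx, sy


def _estimate(method: str, beta: float, se: float, n_snps: int) -> MrEstimate:
    z = beta / se
    pval = float(2 * stats.norm.sf(abs(z)))
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=pval,
        n_snps=n_snps,
    )


def ivw(table: SummaryTable) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    beta_hat = sum(beta_X*beta_Y/se_Y^2) / sum(beta_X^2/se_Y^2),
    SE = sqrt(1/sum(beta_X^2/se_Y^2)); equivalently each Wald ratio weighted
    by the inverse of its squared first-order SE.  With a single instrument
    this collapses to the Wald ratio.
    """
    bx, by, _, sy = _arrays(table)
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return _estimate("IVW", beta, se, len(table))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight-midpoint interpolated weighted median.

    Ratios are sorted ascending (stable, so ties keep input order); with
    normalized weights w, the j-th order statistic sits at cumulative
    position p_j = cumsum(w)_j - w_j/2, and the estimate interpolates the
    ratios linearly at p = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order].astype(float)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise InputError("weighted median: weights must be positive and finite")
    w = w / total
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, r))


def weighted_median(
    table: SummaryTable, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Weights are inverse squared first-order Wald-ratio SEs,
    (beta_X/se_Y)^2.  The point estimate is deterministic; the SE resamples
    beta_X* ~ N(beta_X, se_X) and beta_Y* ~ N(beta_Y, se_Y) per variant and
    is the standard deviation of the recomputed median over ``n_boot``
    replicates.
    """
    bx, by, sx, sy = _arrays(table)
    n = len(bx)
    if n < 3:
        logging.getLogger(__name__).warning(
            "weighted median on %d instrument(s); >=3 recommended", n
        )
    ratios = by / bx
    weights = (bx / sy) ** 2
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boot[b] = _weighted_median(byb[ok] / bxb[ok], (bxb[ok] / sy[ok]) ** 2)
    se = float(np.std(boot, ddof=1))
    return _estimate("weighted_median", est, se, n)


def _loo_slopes(bx: np.ndarray, by, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted regression-through-origin slopes.

    ``by`` may be 1-D (observed) or 2-D (n_sim, n) simulated outcome betas;
    returns slopes of matching shape.
    """
    sxx = np.sum(w * bx**2)
    sxy = np.sum(w * bx * by, axis=-1, keepdims=by.ndim == 2)
    num = sxy - w * bx * by
    den = sxx - w * bx**2
    return num / den


def mr_presso(
    table: SummaryTable,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test with outlier-corrected IVW.

    For each variant j the expected outcome beta under the causal model is
    the leave-one-out IVW slope times beta_Xj; the observed weighted residual
    sum of squares (weights 1/se_Y^2) is compared against ``n_sim`` parametric
    simulations beta_Yj* ~ N(slope_(-j)*beta_Xj, se_Yj) to give a global
    p-value.  Per-variant outlier p-values compare each observed squared
    residual with its simulated distribution, Bonferroni-adjusted by the
    number of variants; flagged variants are removed and IVW re-run.

    The smallest attainable adjusted p is n_snps/(n_sim+1): choose
    ``n_sim`` > n_snps/outlier_alpha or no variant can ever be flagged.
    """
    bx, by, _, sy = _arrays(table)
    n = len(bx)
    if n < 4:
        raise InputError(f"MR-PRESSO needs >= 4 instruments, got {n}")
    if n_sim < 100:
        raise InputError(f"n_sim must be >= 100, got {n_sim}")
    ids = table.df["snp_id"].to_numpy()
    w = 1.0 / sy**2

    slopes = _loo_slopes(bx, by, w)
    res_obs = w * (by - slopes * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(slopes * bx, sy, size=(n_sim, n))
    slopes_sim = _loo_slopes(bx, by_sim, w)
    res_sim = w * (by_sim - slopes_sim * bx) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    raw_p = (1 + np.sum(res_sim >= res_obs, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * n)
    outlier_mask = adj_p < outlier_alpha
    outlier_ids = ids[outlier_mask].tolist()
    if outlier_mask.all():
        raise EstimationError("every instrument flagged as an outlier")

    keep = table.subset(ids[~outlier_mask])
    corrected = ivw(keep)
    corrected = MrEstimate(
        method="MR_PRESSO",
        beta=corrected.beta,
        se=corrected.se,
        ci_low=corrected.ci_low,
        ci_high=corrected.ci_high,
        pval=corrected.pval,
        n_snps=corrected.n_snps,
    )
    return PressoResult(
        global_pval=global_pval,
        outlier_pvals=pd.Series(adj_p, index=ids, name="outlier_pval"),
        outlier_ids=outlier_ids,
        corrected=corrected,
        rss_obs=rss_obs,
        n_simulations=n_sim,
        seed=seed,
    )


@dataclass(frozen=True)
class MrRunConfig:
    """Estimator settings shared by both directions of a bidirectional run."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_boot: int = 1000
    n_sim: int = 1000
    outlier_alpha: float = 0.05
    seed: int | None = None


def run_all_estimators(table: SummaryTable, config: MrRunConfig) -> list[MrEstimate]:
    out = [ivw(table), weighted_median(table, config.n_boot, config.seed)]
    if len(table) >= 4:
        out.append(
            mr_presso(table, config.n_sim, config.outlier_alpha, config.seed).corrected
        )
    return out


def bidirectional_mr(
    forward: SummaryTable,
    reverse: SummaryTable,
    config: MrRunConfig | None = None,
    forward_exclusions: frozenset[str] = frozenset(),
    reverse_exclusions: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Run selection plus IVW / weighted median / outlier-corrected IVW in
    both causal directions, with ('pruned') and without ('all') the
    pleiotropy exclusion lists, returning one tidy results table."""
    config = config or MrRunConfig()
    rows = []
    for direction, table, excl in (
        ("forward", forward, forward_exclusions),
        ("reverse", reverse, reverse_exclusions),
    ):
        for iv_set, exclusion in (("all", frozenset()), ("pruned", frozenset(excl))):
            sel_cfg = SelectionConfig(
                f_threshold=config.selection.f_threshold,
                gwas_p_threshold=config.selection.gwas_p_threshold,
                exclusion_list=exclusion,
            )
            report = select_instruments(table, sel_cfg)
            if len(report.retained) == 0:
                raise EstimationError(f"{direction}/{iv_set}: no instruments retained")
            for est in run_all_estimators(report.retained, config):
                rows.append(
                    {
                        "direction": direction,
                        "iv_set": iv_set,
                        "method": est.method,
                        "n_snps": est.n_snps,
                        "beta": est.beta,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "pval": est.pval,
                    }
                )
    return pd.DataFrame(rows)
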