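"""Synthetic GWAS summary statistics and cohort survival data with known truth.

The GWAS generator emulates a two-sample setting: per-variant exposure
effects are drawn around a typical effect size, outcome effects follow a
linear causal model beta_Y = theta * beta_X plus optional per-variant
pleiotropic shifts (balanced: mean-zero; directional: positive-mean), and
both sides receive sampling noise at their reported standard errors.

The cohort generator emulates a large prospective cohort of postmenopausal
women: a BMI-like continuous exposure (mean 24.3, SD 3.5 kg/m^2), a uric-
acid-like mediator linear in the exposure (marginal SD ~= 75 umol/l), a
block of questionnaire covariates independent of the exposure by default,
and a rare time-to-event outcome (~1% cumulative incidence over 8.2 years)
from a Weibull baseline hazard multiplied by exp(theta1*exposure +
theta2*mediator), inverse-transform sampled, with administrative censoring.
Default effect sizes are one SD of exposure -> HR 1.25 directly and
HR 1.05 through the mediator, so the true proportion mediated is
ln(1.05)/ln(1.3125) ~= 0.178.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .summary_io import SnpRecord, SummaryTable, write_summary_table

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class GwasSimConfig:
    n_snps: int = 60
    true_theta: float = 0.2
    exposure_beta_mean: float = 0.03
    exposure_beta_sd: float = 0.01
    se_exposure: float = 0.002
    se_outcome: float = 0.003
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ConfigurationError("pleiotropy_frac must be in [0, 1]")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ConfigurationError("standard errors must be positive")


@dataclass(frozen=True)
class CohortSimConfig:
    n_subjects: int = 20_000
    exposure_mean: float = 24.3
    exposure_sd: float = 3.5
    mediator_mean: float = 273.1
    beta1: float = 6.0  # mediator units per exposure unit
    mediator_resid_sd: float = 72.0  # marginal mediator SD ~= 75
    theta1: float = float(np.log(1.25) / 3.5)  # log-hazard per exposure unit
    theta2: float = float(np.log(1.05) / (6.0 * 3.5))  # per mediator unit
    baseline_rate: float = 9.44e-4  # Weibull scale, ~1% incidence at defaults
    baseline_shape: float = 1.1
    censor_admin_years: float = 8.2
    dropout_frac: float = 0.0
    confounded: bool = False
    missing_frac: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.exposure_sd <= 0 or self.mediator_resid_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if self.baseline_rate <= 0 or self.baseline_shape <= 0:
            raise ConfigurationError("Weibull baseline must be positive")
        if not (0.0 <= self.dropout_frac <= 1.0):
            raise ConfigurationError("dropout_frac must be in [0, 1]")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ConfigurationError("missing_frac must be in [0, 1)")

    @property
    def true_proportion_mediated(self) -> float:
        """Generator-truth PM on the log-hazard scale for a one-SD contrast."""
        nie = self.theta2 * self.beta1 * self.exposure_sd
        nde = self.theta1 * self.exposure_sd
        return nie / (nde + nie)


def simulate_gwas(config: GwasSimConfig) -> SummaryTable:
    """Draw a harmonized two-sample summary table under a linear causal model.

    Observed betas carry sampling noise at the per-variant SEs; a
    ``pleiotropy_frac`` fraction of variants receives an additional direct
    outcome effect alpha_j ~ N(pleiotropy_mean, pleiotropy_sd).
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    bx_true = rng.normal(config.exposure_beta_mean, config.exposure_beta_sd, n)
    alpha = np.zeros(n)
    n_pleio = int(round(config.pleiotropy_frac * n))
    if n_pleio:
        pleio_idx = rng.choice(n, size=n_pleio, replace=False)
        alpha[pleio_idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n_pleio)
    sx = np.full(n, config.se_exposure)
    sy = np.full(n, config.se_outcome)
    bx = bx_true + rng.normal(0.0, sx)
    by = config.true_theta * bx_true + alpha + rng.normal(0.0, sy)
    alleles = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), n)]
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{1000 + i}" for i in range(n)],
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "beta_exposure": bx,
            "se_exposure": sx,
            "pval_exposure": 2 * stats.norm.sf(np.abs(bx / sx)),
            "beta_outcome": by,
            "se_outcome": sy,
            "pval_outcome": 2 * stats.norm.sf(np.abs(by / sy)),
        }
    )
    return SummaryTable(df, exposure_name="exposure", outcome_name="outcome",
                        source="simulate_gwas")


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate the cohort table consumed by the Cox and mediation routines.

    Columns: id, bmi, waist, ua, the questionnaire covariate block, and the
    realized follow-up (time_years, event).  Covariates are independent of
    the exposure unless ``confounded`` ties age to both exposure and hazard.
    The log hazard uses mean-centered exposure and mediator so the baseline
    rate directly controls the incidence of an average subject.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    age = rng.normal(61.3, 8.0, n)
    bmi = rng.normal(config.exposure_mean, config.exposure_sd, n)
    if config.confounded:
        bmi = bmi + 0.1 * (age - 61.3)
    intercept = config.mediator_mean - config.beta1 * config.exposure_mean
    ua = intercept + config.beta1 * bmi + rng.normal(0.0, config.mediator_resid_sd, n)
    # waist: second adiposity measure, correlated ~0.8 with BMI
    waist = 81.4 + 0.8 * (9.2 / config.exposure_sd) * (bmi - config.exposure_mean) \
        + rng.normal(0.0, 9.2 * np.sqrt(1 - 0.8**2), n)

    eta = (config.theta1 * (bmi - config.exposure_mean)
           + config.theta2 * (ua - config.mediator_mean))
    if config.confounded:
        eta = eta + 0.02 * (age - 61.3)
    # inverse-transform Weibull event times: S(t) = exp(-rate * t^shape * e^eta)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (config.baseline_rate * np.exp(eta))) ** (1.0 / config.baseline_shape)
    censor = np.full(n, config.censor_admin_years)
    if config.dropout_frac > 0:
        lost = rng.uniform(size=n) < config.dropout_frac
        censor[lost] = np.minimum(censor[lost], rng.uniform(0, config.censor_admin_years, lost.sum()))
    time_years = np.minimum(t_event, censor)
    event = t_event <= censor

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "bmi": bmi,
            "waist": waist,
            "ua": ua,
            "age": age,
            "smoking": rng.binomial(1, 0.04, n).astype(float),
            "drinking": rng.binomial(1, 0.09, n).astype(float),
            "education": rng.binomial(1, 0.38, n).astype(float),
            "marital": rng.binomial(1, 0.145, n).astype(float),
            "batch": rng.binomial(1, 0.34, n).astype(float),
            "parity": np.clip(rng.poisson(2.0, n), 0, 6).astype(float),
            "menopause_age": rng.normal(49.1, 3.7, n),
            "mastitis": rng.binomial(1, 0.05, n).astype(float),
            "diuretics": rng.binomial(1, 0.019, n).astype(float),
            "antibiotics": rng.binomial(1, 0.087, n).astype(float),
            "hrt": rng.binomial(1, 0.031, n).astype(float),
            "time_years": time_years,
            "event": event.astype(int),
        }
    )
    if config.missing_frac > 0:
        for col in ("bmi", "ua", "waist", "menopause_age", "mastitis"):
            mask = rng.uniform(size=n) < config.missing_frac
            df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# fixture suite


def _three_snp_records() -> tuple[list[SnpRecord], list[SnpRecord]]:
    """Tiny deterministic exposure/outcome pair: one aligned, one with
    swapped alleles (sign-flip on harmonization), one aligned negative."""
    exposure = [
        SnpRecord("rs1", "A", "G", 0.05, 0.004, 1e-30),
        SnpRecord("rs2", "T", "C", 0.04, 0.004, 1e-22),
        SnpRecord("rs3", "G", "A", -0.03, 0.004, 1e-13),
    ]
    outcome = [
        SnpRecord("rs1", "A", "G", 0.010, 0.003, 8.6e-4),
        SnpRecord("rs2", "C", "T", -0.008, 0.003, 7.7e-3),
        SnpRecord("rs3", "G", "A", -0.006, 0.003, 4.6e-2),
    ]
    return exposure, outcome


def _five_subject_cox() -> pd.DataFrame:
    """Five subjects, one binary covariate, distinct times (no ties)."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5],
            "x": [1.0, 1.0, 0.0, 0.0, 1.0],
            "time_years": [1.0, 2.5, 3.0, 4.5, 6.0],
            "event": [1, 0, 1, 1, 0],
        }
    )


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the small test fixtures plus a manifest of ground-truth
    parameters; returns the manifest.

    Deterministic fixtures (3-variant tables, 5-subject survival fixture)
    are identical for every seed; the stochastic ones (null / effect /
    outlier GWAS tables, default cohort) derive child seeds from ``seed``.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    exp_rec, out_rec = _three_snp_records()
    write_summary_table(exp_rec, out / "three_snp_exposure.tsv")
    write_summary_table(out_rec, out / "three_snp_outcome.tsv")
    _five_subject_cox().to_csv(out / "five_subject_cox.csv", index=False)

    effect_cfg = GwasSimConfig(n_snps=50, true_theta=0.2, seed=child[0])
    null_cfg = GwasSimConfig(n_snps=50, true_theta=0.0, seed=child[1])
    effect = simulate_gwas(effect_cfg)
    null = simulate_gwas(null_cfg)
    effect.to_tsv(out / "gwas_effect.tsv")
    null.to_tsv(out / "gwas_null.tsv")
    write_summary_table(effect.exposure_records(), out / "gwas_effect_exposure.tsv")
    write_summary_table(effect.outcome_records(), out / "gwas_effect_outcome.tsv")
    write_summary_table(null.exposure_records(), out / "gwas_null_exposure.tsv")
    write_summary_table(null.outcome_records(), out / "gwas_null_outcome.tsv")

    outlier = effect.df.copy()
    outlier.loc[0, "beta_outcome"] += 10 * outlier.loc[0, "se_outcome"]
    SummaryTable(outlier).to_tsv(out / "gwas_outlier.tsv")

    cohort_cfg = CohortSimConfig(seed=child[2])
    cohort = simulate_cohort(cohort_cfg)
    cohort.to_csv(out / "cohort_default.csv", index=False)

    manifest = {
        "seed": seed,
        "fixtures": {
            "three_snp_exposure.tsv": {"kind": "deterministic"},
            "three_snp_outcome.tsv": {"kind": "deterministic"},
            "five_subject_cox.csv": {"kind": "deterministic"},
            "gwas_effect.tsv": {"kind": "stochastic", "config": asdict(effect_cfg)},
            "gwas_null.tsv": {"kind": "stochastic", "config": asdict(null_cfg)},
            "gwas_outlier.tsv": {
                "kind": "stochastic",
                "note": "gwas_effect with variant 0 outcome beta displaced by +10 SE",
            },
            "cohort_default.csv": {
                "kind": "stochastic",
                "config": asdict(cohort_cfg),
                "true_proportion_mediated": cohort_cfg.true_proportion_mediated,
                "realized_events": int(cohort["event"].sum()),
            },
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def file_checksum(path) -> str:
    """SHA-256 of a file, for reproducibility checks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
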