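"""Read, validate, harmonize and write two-sample GWAS summary statistics.

A two-sample Mendelian randomization analysis consumes per-variant effect
estimates from two independent GWAS: one of the exposure trait and one of the
outcome trait.  Before any estimator can run, the two tables have to be merged
on variant id and their effect alleles aligned, flipping the sign of the
outcome beta whenever the outcome study reported the other strand-consistent
allele orientation.  Variants absent from the outcome study, or with alleles
that can be neither matched nor swapped, are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Default header names for summary-statistic files.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

#: Strand-ambiguous allele pairs (identical on both strands).
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class SnpRecord:
    """One variant's association with a single trait.

    ``beta`` is the per-effect-allele effect on the (possibly transformed)
    trait; ``se`` its standard error; ``pval`` the association p-value.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise InputError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0.0 <= self.pval <= 1.0):
            raise InputError(f"{self.snp_id}: pval outside [0,1]: {self.pval}")
        if self.effect_allele.upper() == self.other_allele.upper():
            raise InputError(f"{self.snp_id}: effect and other allele are identical")

    @property
    def is_palindromic(self) -> bool:
        pair = frozenset({self.effect_allele.upper(), self.other_allele.upper()})
        return pair in _PALINDROMIC


class ParseResult(NamedTuple):
    records: list[SnpRecord]
    n_dropped: int


class SummaryTable:
    """Harmonized exposure/outcome summary statistics, one row per variant.

    Wraps a :class:`pandas.DataFrame` with columns ``snp_id``,
    ``effect_allele``, ``other_allele`` (exposure orientation),
    ``beta_exposure``, ``se_exposure``, ``pval_exposure``, ``beta_outcome``,
    ``se_outcome``, ``pval_outcome``.  Variant ids are unique; all SEs are
    strictly positive.
    """

    COLUMNS = [
        "snp_id",
        "effect_allele",
        "other_allele",
        "beta_exposure",
        "se_exposure",
        "pval_exposure",
        "beta_outcome",
        "se_outcome",
        "pval_outcome",
    ]

    def __init__(
        self,
        df: pd.DataFrame,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        source: str | None = None,
    ) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"SummaryTable missing columns: {missing}")
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise InputError(f"duplicate snp_ids: {dups}")
        for c in ("se_exposure", "se_outcome"):
            bad = df[~(df[c] > 0)]
            if len(bad):
                raise InputError(f"non-positive {c} for {bad['snp_id'].tolist()}")
        self.df = df.reset_index(drop=True)[self.COLUMNS].copy()
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.source = source

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def subset(self, snp_ids: Iterable[str]) -> "SummaryTable":
        """Row subset preserving input order."""
        keep = set(snp_ids)
        return SummaryTable(
            self.df[self.df["snp_id"].isin(keep)].reset_index(drop=True),
            self.exposure_name,
            self.outcome_name,
            self.source,
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "SummaryTable":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise InputError(f"{path}: empty summary table")
        return cls(df, **kwargs)

    def exposure_records(self) -> list[SnpRecord]:
        return [
            SnpRecord(r.snp_id, r.effect_allele, r.other_allele,
                      r.beta_exposure, r.se_exposure, r.pval_exposure)
            for r in self.df.itertuples()
        ]

    def outcome_records(self) -> list[SnpRecord]:
        return [
            SnpRecord(r.snp_id, r.effect_allele, r.other_allele,
                      r.beta_outcome, r.se_outcome, r.pval_outcome)
            for r in self.df.itertuples()
        ]


@dataclass
class HarmonizationResult:
    table: SummaryTable
    n_dropped_missing: int
    n_dropped_inconsistent: int
    n_palindromic: int = 0
    dropped_missing_ids: list[str] = field(default_factory=list)
    dropped_inconsistent_ids: list[str] = field(default_factory=list)


def read_summary_table(
    path, column_map: Mapping[str, str] | None = None
) -> ParseResult:
    """Parse a delimited summary-statistic file into :class:`SnpRecord` rows.

    ``column_map`` maps field names (``snp_id``, ``effect_allele``, ...) to
    header names in the file; unspecified fields fall back to
    :data:`DEFAULT_COLUMN_MAP`.  Rows whose beta/se/pval cannot be parsed (or
    violate record invariants) are dropped and counted; the count is logged
    and returned.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    missing = [cmap[f] for f in _MANDATORY if cmap[f] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mandatory columns missing from header: {missing}"
        )
    if raw.empty:
        raise InputError(f"{path}: no data rows")
    has_n = cmap["n"] in raw.columns

    records: list[SnpRecord] = []
    n_dropped = 0
    for _, row in raw.iterrows():
        try:
            beta = float(row[cmap["beta"]])
            se = float(row[cmap["se"]])
            pval = float(row[cmap["pval"]])
            if not (np.isfinite(beta) and np.isfinite(se) and np.isfinite(pval)):
                raise ValueError("non-finite value")
            n = None
            if has_n and not pd.isna(row[cmap["n"]]):
                n = int(float(row[cmap["n"]]))
            records.append(
                SnpRecord(
                    snp_id=str(row[cmap["snp_id"]]),
                    effect_allele=str(row[cmap["effect_allele"]]),
                    other_allele=str(row[cmap["other_allele"]]),
                    beta=beta,
                    se=se,
                    pval=pval,
                    n=n,
                )
            )
        except (ValueError, TypeError, InputError) as exc:
            n_dropped += 1
            logger.warning("%s: dropping row %r (%s)", path, row.iloc[0], exc)
    if n_dropped:
        logger.info("%s: dropped %d unparseable rows", path, n_dropped)
    return ParseResult(records, n_dropped)


def write_summary_table(records: Sequence[SnpRecord], path,
                        column_map: Mapping[str, str] | None = None) -> None:
    """Write records as a tab-separated file (inverse of :func:`read_summary_table`)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.DataFrame(
        {
            cmap["snp_id"]: [r.snp_id for r in records],
            cmap["effect_allele"]: [r.effect_allele for r in records],
            cmap["other_allele"]: [r.other_allele for r in records],
            cmap["beta"]: [r.beta for r in records],
            cmap["se"]: [r.se for r in records],
            cmap["pval"]: [r.pval for r in records],
            cmap["n"]: [r.n if r.n is not None else "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: Sequence[SnpRecord],
    outcome: Sequence[SnpRecord],
    drop_palindromic: bool = False,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizationResult:
    """Inner-join exposure and outcome records on variant id, aligning alleles.

    If the outcome study's effect/other alleles are swapped relative to the
    exposure study, the outcome beta is sign-flipped.  Variants with
    inconsistent alleles (neither matched nor swapped) are dropped, as are
    variants missing from the outcome set.  Strand-ambiguous (A/T, C/G)
    variants are kept with a warning by default because resolving them
    requires allele frequencies; ``drop_palindromic`` removes them (counted
    under ``n_dropped_inconsistent``).
    """
    out_by_id = {r.snp_id: r for r in outcome}
    rows = []
    missing_ids: list[str] = []
    inconsistent_ids: list[str] = []
    n_palindromic = 0
    for ex in exposure:
        ov = out_by_id.get(ex.snp_id)
        if ov is None:
            missing_ids.append(ex.snp_id)
            continue
        ea, oa = ex.effect_allele.upper(), ex.other_allele.upper()
        oea, ooa = ov.effect_allele.upper(), ov.other_allele.upper()
        if (ea, oa) == (oea, ooa):
            beta_out = ov.beta
        elif (ea, oa) == (ooa, oea):
            beta_out = -ov.beta
        else:
            inconsistent_ids.append(ex.snp_id)
            continue
        if ex.is_palindromic:
            n_palindromic += 1
            if drop_palindromic:
                inconsistent_ids.append(ex.snp_id)
                continue
            logger.warning(
                "%s: palindromic alleles %s/%s kept without frequency check",
                ex.snp_id, ea, oa,
            )
        rows.append(
            {
                "snp_id": ex.snp_id,
                "effect_allele": ex.effect_allele,
                "other_allele": ex.other_allele,
                "beta_exposure": ex.beta,
                "se_exposure": ex.se,
                "pval_exposure": ex.pval,
                "beta_outcome": beta_out,
                "se_outcome": ov.se,
                "pval_outcome": ov.pval,
            }
        )
    if not rows:
        raise InputError("no overlapping variants between exposure and outcome")
    table = SummaryTable(
        pd.DataFrame(rows), exposure_name=exposure_name, outcome_name=outcome_name
    )
    if missing_ids:
        logger.info("harmonize: %d variants missing from outcome set", len(missing_ids))
    if inconsistent_ids:
        logger.info("harmonize: %d variants with inconsistent alleles", len(inconsistent_ids))
    return HarmonizationResult(
        table=table,
        n_dropped_missing=len(missing_ids),
        n_dropped_inconsistent=len(inconsistent_ids),
        n_palindromic=n_palindromic,
        dropped_missing_ids=missing_ids,
        dropped_inconsistent_ids=inconsistent_ids,
    )
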