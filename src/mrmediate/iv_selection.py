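"""Instrument quality control for two-sample Mendelian randomization.

A genetic variant qualifies as an instrument when it is robustly associated
with the exposure (genome-wide significance, conventionally p < 5e-8) and
strong enough not to introduce weak-instrument bias (F >= 10).  Variants
known to associate with traits other than the exposure — candidates for
horizontal pleiotropy — are removed via an explicit exclusion list of
variant ids (e.g. compiled from a phenotype-association database).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .summary_io import SummaryTable


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument filters, applied in order: exposure p-value, F, exclusion list."""

    f_threshold: float = 10.0
    gwas_p_threshold: float = 5e-8
    exclusion_list: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.f_threshold < 0:
            raise InputError(f"f_threshold must be >= 0, got {self.f_threshold}")
        if not (0 < self.gwas_p_threshold <= 1):
            raise InputError(
                f"gwas_p_threshold must be in (0,1], got {self.gwas_p_threshold}"
            )
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass
class SelectionReport:
    retained: SummaryTable
    f_values: pd.Series  # indexed by snp_id, for every input variant
    n_removed_pvalue: int
    n_removed_weak: int
    n_removed_pleiotropy: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_pvalue + self.n_removed_weak + self.n_removed_pleiotropy


def f_statistic(beta_exposure, se_exposure):
    """Per-variant instrument-strength F, the squared Wald z: (beta/se)^2.

    Accepts scalars or arrays; the only form computable from summary
    statistics alone.
    """
    beta = np.asarray(beta_exposure, dtype=float)
    se = np.asarray(se_exposure, dtype=float)
    if np.any(~(se > 0)):
        raise InputError("se_exposure must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def select_instruments(table: SummaryTable, config: SelectionConfig) -> SelectionReport:
    """Apply the instrument filters; a variant failing several is counted once,
    under the first failed criterion in the order p-value, F, exclusion list.
    The retained table preserves input order."""
    if len(table) == 0:
        raise InputError("cannot select instruments from an empty table")
    df = table.df
    f_vals = pd.Series(
        f_statistic(df["beta_exposure"].to_numpy(), df["se_exposure"].to_numpy()),
        index=df["snp_id"].to_numpy(),
        name="F",
    )
    fail_p = (df["pval_exposure"] > config.gwas_p_threshold).to_numpy()
    fail_f = (f_vals.to_numpy() < config.f_threshold)
    fail_x = df["snp_id"].isin(config.exclusion_list).to_numpy()

    n_removed_pvalue = int(fail_p.sum())
    n_removed_weak = int((fail_f & ~fail_p).sum())
    n_removed_pleiotropy = int((fail_x & ~fail_p & ~fail_f).sum())

    keep = ~(fail_p | fail_f | fail_x)
    retained = SummaryTable(
        df[keep].reset_index(drop=True),
        table.exposure_name,
        table.outcome_name,
        table.source,
    ) if keep.any() else _empty_like(table)
    return SelectionReport(
        retained=retained,
        f_values=f_vals,
        n_removed_pvalue=n_removed_pvalue,
        n_removed_weak=n_removed_weak,
        n_removed_pleiotropy=n_removed_pleiotropy,
    )


def _empty_like(table: SummaryTable) -> SummaryTable:
    empty = SummaryTable.__new__(SummaryTable)
    empty.df = table.df.iloc[0:0].reset_index(drop=True)
    empty.exposure_name = table.exposure_name
    empty.outcome_name = table.outcome_name
    empty.source = table.source
    return empty


def read_exclusion_list(path) -> frozenset[str]:
    """Read a plain-text exclusion list, one variant id per line; '#' comments
    and blank lines ignored."""
    ids = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return frozenset(ids)
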