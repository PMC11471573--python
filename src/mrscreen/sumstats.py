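"""GWAS summary-statistics data model and tab-delimited I/O.

The whole pipeline exchanges per-SNP association summary statistics in one
strict internal dialect: tab-separated, header row, canonical columns

    snp  chr  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``beta``/``se``/``pval`` are mandatory; ``eaf`` (effect-allele frequency) and
``n`` (sample size) are optional and encoded ``NA`` when absent.  Coordinates
are 1-based.  Only biallelic SNPs with single-character A/C/G/T alleles are
accepted; rows violating any record invariant are dropped with a logged count.
A user-supplied column mapping adapts files with other headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of the internal dialect.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

#: Columns that must be resolvable in every input file.
MANDATORY_COLUMNS: tuple[str, ...] = (
    "snp", "chr", "pos", "effect_allele", "other_allele", "beta", "se", "pval",
)

VALID_ALLELES = frozenset("ACGT")


class SumStatsError(ValueError):
    """Raised for unreadable, malformed or empty summary-statistics input."""


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association summary statistics for one trait.

    ``beta`` is the per-allele additive effect of ``effect_allele`` (log-odds
    for binary outcomes, SD units for continuous traits), ``se`` its standard
    error.  ``eaf``/``n`` may be None.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not _record_valid(self.effect_allele, self.other_allele, self.pos,
                             self.eaf, self.se, self.pval):
            raise SumStatsError(f"invalid summary-statistic record for {self.snp_id}")


def _record_valid(ea: str, oa: str, pos, eaf, se, pval) -> bool:
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
        return False
    if not np.isfinite(se) or se <= 0:
        return False
    if not np.isfinite(pval) or not (0 < pval <= 1):
        return False
    if eaf is not None and not (np.isnan(eaf) or 0 < eaf < 1):
        return False
    if pos < 1:
        return False
    return True


@dataclass
class GwasSumStats:
    """Validated summary statistics for a single trait.

    ``records`` is a DataFrame with the canonical columns; missing ``eaf``/``n``
    are NaN / pandas-NA.  SNP ids are unique within a trait and row order is
    meaningful (it is preserved by I/O and filtering).
    """

    trait_id: str
    records: pd.DataFrame
    trait_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise SumStatsError(f"records missing canonical columns: {missing}")
        if self.records["snp"].duplicated().any():
            dup = self.records.loc[self.records["snp"].duplicated(), "snp"].iloc[0]
            raise SumStatsError(f"duplicate snp id within trait {self.trait_id!r}: {dup!r}")
        self.records = self.records.reset_index(drop=True)
        if not self.trait_label:
            self.trait_label = self.trait_id

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return self.records["snp"].tolist()

    def subset(self, snp_ids: Sequence[str]) -> "GwasSumStats":
        """Rows for ``snp_ids``, in the given order."""
        idx = self.records.set_index("snp").loc[list(snp_ids)].reset_index()
        return GwasSumStats(self.trait_id, idx[list(CANONICAL_COLUMNS)], self.trait_label)

    def iter_records(self):
        for row in self.records.itertuples(index=False):
            yield SumStatRecord(
                snp_id=row.snp, chrom=row.chr, pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                beta=float(row.beta), se=float(row.se), pval=float(row.pval),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else int(row.n),
            )


def _to_float(series: pd.Series) -> pd.Series:
    """Exact (correctly rounded) numeric conversion; invalid entries -> NaN.

    ``pd.to_numeric``'s fast parser is not round-trip exact, so decimal
    strings go through Python's ``float`` instead.
    """
    def conv(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan
    return series.map(conv).astype(float)


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalise dtypes; alleles uppercased; eaf/n optional."""
    out = pd.DataFrame()
    out["snp"] = df["snp"].astype(str)
    out["chr"] = df["chr"].astype(str)
    out["pos"] = _to_float(df["pos"])
    out["effect_allele"] = df["effect_allele"].astype(str).str.upper().str.strip()
    out["other_allele"] = df["other_allele"].astype(str).str.upper().str.strip()
    out["eaf"] = _to_float(df["eaf"]) if "eaf" in df else np.nan
    out["beta"] = _to_float(df["beta"])
    out["se"] = _to_float(df["se"])
    out["pval"] = _to_float(df["pval"])
    out["n"] = _to_float(df["n"]) if "n" in df else np.nan
    return out


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Row-wise invariant enforcement.

    Returns the kept rows (order preserved, canonical dtypes) and the number
    dropped.  The kept/dropped partition depends only on each row's own
    values, never on row order.
    """
    df = _coerce_frame(df)
    ea, oa = df["effect_allele"], df["other_allele"]
    keep = (
        ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES) & (ea != oa)
        & df["beta"].notna() & np.isfinite(df["beta"].to_numpy(float))
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & df["pos"].notna() & (df["pos"] >= 1)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
        & (df["n"].isna() | (df["n"] > 0))
    )
    kept = df.loc[keep].copy()
    kept["pos"] = kept["pos"].astype(np.int64)
    kept["n"] = kept["n"].round().astype("Int64")
    n_dropped = int((~keep).sum())
    return kept.reset_index(drop=True), n_dropped


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_label: str = "",
) -> GwasSumStats:
    """Read one trait's summary statistics from a tab-delimited file.

    Parameters
    ----------
    path
        TSV file (gzip accepted by ``.gz`` extension), header row required.
    dialect
        Mapping from canonical column names to the file's header names, for
        files not already in the canonical dialect, e.g.
        ``{"snp": "rsid", "pval": "p"}``.  Unmapped canonical names are looked
        up verbatim.
    trait_id
        Defaults to the file stem.

    Rows violating record invariants are dropped with a logged count.
    Missing mandatory columns and files that are empty after filtering are
    hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise SumStatsError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=False)
    dialect = dict(dialect or {})
    rename: dict[str, str] = {}
    for canonical in CANONICAL_COLUMNS:
        source = dialect.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise SumStatsError(
                f"{path}: mandatory column {canonical!r} (file header {source!r}) not found"
            )
    df = raw.rename(columns=rename)
    kept, n_dropped = validate_records(df)
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    if kept.empty:
        raise SumStatsError(f"{path}: no valid summary-statistic rows after filtering")
    tid = trait_id if trait_id is not None else path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return GwasSumStats(tid, kept, trait_label)


def write_sumstats(stats: GwasSumStats, path: str | Path) -> None:
    """Write ``stats`` in the canonical dialect (``NA`` for missing values).

    Refuses to emit an empty trait.  ``read_sumstats(write_sumstats(x))``
    reproduces ``x`` field-for-field, including optional-field absence.
    """
    if len(stats) == 0:
        raise SumStatsError(f"refusing to write empty trait {stats.trait_id!r}")
    out = stats.records[list(CANONICAL_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
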