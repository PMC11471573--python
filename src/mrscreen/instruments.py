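"""Instrumental-variable selection per exposure.

Three rules, applied in order:

1. genome-wide significance filter (p strictly below 5e-8 by default);
2. greedy LD clumping (discard SNPs with r-squared > 0.001 to a more
   significant index SNP within a +/-10,000 kb window on the same chromosome);
3. instrument-strength filter, per-SNP F = (beta/se)^2 >= 10, the standard
   summary-data approximation to the first-stage F.

A trait may end with an empty instrument set; it is then excluded from
analysis (and reported), mirroring the attrition seen when screening large
trait panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LdProvider
from .sumstats import CANONICAL_COLUMNS, GwasSumStats, SumStatRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet", "f_statistic", "filter_significant", "clump_greedy",
    "build_instrument_set",
]


@dataclass
class InstrumentSet:
    """Post-filter, post-clump instruments for one exposure, with F statistics."""

    trait_id: str
    snps: pd.DataFrame            # canonical sumstats columns, clump order
    f_stats: np.ndarray           # per-SNP F, aligned with ``snps`` rows
    n_before_clump: int
    n_after_clump: int

    @property
    def is_empty(self) -> bool:
        return len(self.snps) == 0

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp"].tolist()

    @property
    def min_f(self) -> float:
        return float(np.min(self.f_stats)) if len(self.f_stats) else float("nan")

    @property
    def max_f(self) -> float:
        return float(np.max(self.f_stats)) if len(self.f_stats) else float("nan")

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stats)) if len(self.f_stats) else float("nan")

    def as_sumstats(self) -> GwasSumStats:
        return GwasSumStats(self.trait_id, self.snps[list(CANONICAL_COLUMNS)])


def f_statistic(record: SumStatRecord | pd.Series) -> float:
    """Per-SNP instrument strength, F = (beta / se)^2."""
    if isinstance(record, SumStatRecord):
        return (record.beta / record.se) ** 2
    return float((record["beta"] / record["se"]) ** 2)


def filter_significant(stats: GwasSumStats, p_threshold: float = 5e-8) -> GwasSumStats:
    """Keep exactly the records with p strictly below ``p_threshold``.

    Order is preserved; the result may be empty (callers flag such traits).
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    kept = stats.records.loc[stats.records["pval"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        return _empty_like(stats)
    return GwasSumStats(stats.trait_id, kept, stats.trait_label)


def _empty_like(stats: GwasSumStats) -> GwasSumStats:
    out = GwasSumStats.__new__(GwasSumStats)
    out.trait_id = stats.trait_id
    out.trait_label = stats.trait_label
    out.records = stats.records.iloc[0:0].reset_index(drop=True)
    return out


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    # p-value ties broken by (chrom, pos, snp_id) for determinism
    return df.sort_values(["pval", "chr", "pos", "snp"], kind="mergesort")


def clump_greedy(
    stats: GwasSumStats,
    ld: LdProvider,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> GwasSumStats:
    """Greedy p-value-ordered LD clumping.

    Repeatedly promote the most significant remaining SNP to index status and
    discard every other remaining SNP on the same chromosome within
    +/-``window_kb`` whose r-squared with the index exceeds ``r2_threshold``.
    Index SNPs are returned sorted by ascending p-value.  A pair the LD
    provider does not know, inside the window, is conservatively treated as
    r-squared 1 (removed) with a warning; cross-chromosome/window pairs never
    consult the provider.
    """
    df = _clump_order(stats.records)
    window_bp = float(window_kb) * 1_000.0
    remaining = list(df.itertuples(index=False))
    kept_ids: list[str] = []
    warned = False
    while remaining:
        index_snp = remaining.pop(0)
        kept_ids.append(index_snp.snp)
        survivors = []
        for other in remaining:
            if other.chr == index_snp.chr and abs(other.pos - index_snp.pos) <= window_bp:
                r2 = ld.r2(index_snp.snp, other.snp)
                if r2 is None:
                    if not warned:
                        logger.warning(
                            "%s: LD unknown for in-window pair (%s, %s); "
                            "treating r2 as 1 (conservative removal)",
                            stats.trait_id, index_snp.snp, other.snp)
                        warned = True
                    r2 = 1.0
                if r2 > r2_threshold:
                    continue
            survivors.append(other)
        remaining = survivors
    if not kept_ids:
        return _empty_like(stats)
    out = stats.subset(kept_ids)
    return GwasSumStats(stats.trait_id, out.records, stats.trait_label)


def build_instrument_set(
    stats: GwasSumStats,
    ld: LdProvider,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    f_threshold: float = 10.0,
) -> InstrumentSet:
    """Significance filter, then clumping, then the F >= threshold filter."""
    sig = filter_significant(stats, p_threshold)
    n_before = len(sig)
    if n_before == 0:
        logger.info("%s: no eligible IVs at p < %g", stats.trait_id, p_threshold)
        return InstrumentSet(stats.trait_id, sig.records, np.empty(0), 0, 0)
    clumped = clump_greedy(sig, ld, r2_threshold, window_kb)
    n_after = len(clumped)
    f = (clumped.records["beta"] / clumped.records["se"]) ** 2
    strong = clumped.records.loc[f.to_numpy() >= f_threshold].reset_index(drop=True)
    return InstrumentSet(
        trait_id=stats.trait_id,
        snps=strong,
        f_stats=f.to_numpy()[f.to_numpy() >= f_threshold],
        n_before_clump=n_before,
        n_after_clump=n_after,
    )
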