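"""Allele harmonization of exposure and outcome summary statistics.

Before any estimator can combine per-SNP effects from two GWAS, both must
report the effect of the *same* allele.  For each SNP shared by the two
datasets:

* same allele pair, same orientation -> ``aligned`` (nothing to do);
* same pair, swapped orientation -> outcome beta sign-flipped and its
  effect-allele frequency complemented (``flipped``);
* palindromic pair (A/T or C/G, strand-ambiguous) -> orientation inferred
  from effect-allele frequencies: after any orientation flip both frequencies
  must sit on the same side of 0.5; if either frequency is missing or too
  close to 0.5 (within ``eaf_ambiguity_halfwidth``, default 0.08) the SNP is
  dropped (``dropped_palindromic``);
* different allele pairs -> ``dropped_mismatch`` (with ``allow_strand_flip``
  a complementary-strand recoding is attempted first for non-palindromic
  SNPs; off by default because silent strand rescue risks sign errors).

Dropped records carry a status but no usable effect estimates and are
excluded by :func:`analysis_ready` before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sumstats import GwasSumStats

__all__ = [
    "HarmonizedPair", "is_palindromic", "harmonize_pair", "analysis_ready",
    "ALIGNED", "FLIPPED", "PALINDROMIC_ALIGNED", "DROPPED_PALINDROMIC",
    "DROPPED_MISMATCH",
]

ALIGNED = "aligned"
FLIPPED = "flipped"
PALINDROMIC_ALIGNED = "palindromic_aligned"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"
_DROPPED = frozenset({DROPPED_PALINDROMIC, DROPPED_MISMATCH})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP on a common effect-allele orientation."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    status: str
    eaf_x: float | None = None
    eaf_y: float | None = None

    @property
    def dropped(self) -> bool:
        return self.status in _DROPPED


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    return _COMPLEMENT.get(effect_allele.upper()) == other_allele.upper()


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)


def harmonize_pair(
    exposure: GwasSumStats,
    outcome: GwasSumStats,
    eaf_ambiguity_halfwidth: float = 0.08,
    allow_strand_flip: bool = False,
) -> list[HarmonizedPair]:
    """Harmonize the SNP intersection of two traits onto the exposure's alleles.

    Returns one :class:`HarmonizedPair` per shared SNP, in exposure row order,
    including dropped records (with their drop status) for the harmonization
    log.
    """
    out_by_snp = {r.snp: r for r in outcome.records.itertuples(index=False)}
    pairs: list[HarmonizedPair] = []
    for ex in exposure.records.itertuples(index=False):
        oc = out_by_snp.get(ex.snp)
        if oc is None:
            continue
        pairs.append(_harmonize_one(ex, oc, eaf_ambiguity_halfwidth, allow_strand_flip))
    return pairs


def _harmonize_one(ex, oc, halfwidth: float, allow_strand_flip: bool) -> HarmonizedPair:
    ea_x, oa_x = ex.effect_allele, ex.other_allele
    ea_y, oa_y = oc.effect_allele, oc.other_allele
    beta_y, eaf_y = float(oc.beta), _opt(oc.eaf)
    eaf_x = _opt(ex.eaf)
    pal = is_palindromic(ea_x, oa_x)

    if {ea_x, oa_x} != {ea_y, oa_y}:
        if allow_strand_flip and not pal and \
                {_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]} == {ea_x, oa_x}:
            ea_y, oa_y = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
        else:
            return _pair(ex, oc, beta_y, eaf_x, eaf_y, DROPPED_MISMATCH)

    if not pal:
        if ea_y == ea_x:
            return _pair(ex, oc, beta_y, eaf_x, eaf_y, ALIGNED)
        beta_y = -beta_y
        eaf_y = None if eaf_y is None else 1.0 - eaf_y
        return _pair(ex, oc, beta_y, eaf_x, eaf_y, FLIPPED)

    # Palindromic: alleles alone cannot fix the strand; use frequencies.
    if eaf_x is None or eaf_y is None or \
            abs(eaf_x - 0.5) < halfwidth or abs(eaf_y - 0.5) < halfwidth:
        return _pair(ex, oc, beta_y, eaf_x, eaf_y, DROPPED_PALINDROMIC)
    if ea_y != ea_x:  # recorded with swapped orientation
        beta_y = -beta_y
        eaf_y = 1.0 - eaf_y
    if (eaf_x < 0.5) != (eaf_y < 0.5):  # opposite strands: flip the outcome
        beta_y = -beta_y
        eaf_y = 1.0 - eaf_y
    return _pair(ex, oc, beta_y, eaf_x, eaf_y, PALINDROMIC_ALIGNED)


def _pair(ex, oc, beta_y, eaf_x, eaf_y, status) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=ex.snp,
        beta_x=float(ex.beta), se_x=float(ex.se),
        beta_y=float(beta_y), se_y=float(oc.se),
        status=status, eaf_x=eaf_x, eaf_y=eaf_y,
    )


def analysis_ready(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """The non-dropped pairs; the only pairs estimators will accept."""
    return [p for p in pairs if not p.dropped]


def harmonization_log(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Tidy per-SNP log: snp, status, reason."""
    reasons = {
        DROPPED_PALINDROMIC: "palindromic with ambiguous or missing allele frequency",
        DROPPED_MISMATCH: "allele pair mismatch between datasets",
    }
    return pd.DataFrame({
        "snp": [p.snp_id for p in pairs],
        "status": [p.status for p in pairs],
        "reason": [reasons.get(p.status, "") for p in pairs],
    })
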