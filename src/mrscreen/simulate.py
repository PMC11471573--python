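"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the three-cornered data of a two-step Mendelian
randomization study: an exposure (e.g. a plasma lipid species), a candidate
mediator (e.g. a circulating immune-cell phenotype) and a disease outcome,
each observed only through per-SNP association summary statistics from
non-overlapping GWAS samples.

Generative model (per SNP j)
----------------------------
* exposure instruments:   gamma_j ~ Normal(0, gamma_sd^2), else 0
* mediator instruments:   d_j     ~ Normal(0, delta_sd^2), else 0
  (a disjoint SNP set — each trait is instrumented by its own loci, as when
  exposure and mediator GWAS hits map to different regions of the genome)
* mediator true effect:   delta_j = beta_em * gamma_j + d_j
* outcome true effect:    Gamma_j = theta_direct * gamma_j
                                    + beta_mo * delta_j + alpha_j
  with horizontal pleiotropy alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd^2)
* observed beta = true effect + Normal(0, se^2), with the analytic standard
  error se = 1 / sqrt(2 p_j (1 - p_j) n) at minor-allele frequency p_j and
  the trait's GWAS sample size n; two-sided normal p-values.

Summary statistics are simulated directly on this scale rather than via
individual-level genotypes: two-sample MR consumes only summary data, and
the truth (gamma, delta, Gamma, alpha, and the implied total effect
beta0 = theta_direct + beta_em * beta_mo) stays exactly known.  Outcome betas
are interpreted as log-odds but drawn on the linear scale; the MR algebra is
scale-agnostic.  Draws for the three traits are mutually independent
(non-overlapping samples).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import CANONICAL_COLUMNS, GwasSumStats

__all__ = [
    "CausalScenario", "LdBlockSpec", "TripletTruth",
    "simulate_triplet", "ld_matrix",
    "simulate_exposure_screen", "simulate_mediation_screen",
]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPAL_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
# Distinct LD blocks are placed further apart than any clumping window.
_BLOCK_SPACING_BP = 25_000_000
_WITHIN_BLOCK_SPACING_BP = 5_000
_N_CHROMS = 22


@dataclass(frozen=True)
class CausalScenario:
    """Study conditions for one exposure → mediator → outcome triplet.

    Defaults describe a well-powered two-step MR setting: 30 exposure
    instruments from a ~50k-sample continuous-trait GWAS, 30 mediator-specific
    instruments from a smaller (~5k) cytometry-style GWAS, a large outcome
    GWAS, a mediated chain beta_em=0.5, beta_mo=0.4 on top of a direct effect
    theta_direct=0.1 (total effect beta0 = 0.3), and no horizontal pleiotropy.
    """

    m_snps: int = 70
    m_instruments: int = 30
    m_mediator_instruments: int = 30
    theta_direct: float = 0.1
    beta_em: float = 0.5
    beta_mo: float = 0.4
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    gamma_sd: float = 0.1
    delta_sd: float = 0.15
    n_exposure: int = 50_000
    n_mediator: int = 5_000
    n_outcome: int = 36_000
    maf_range: tuple[float, float] = (0.05, 0.45)
    palindromic_fraction: float = 0.2
    ambiguous_palindromes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.m_instruments <= self.m_snps):
            raise ValueError("need 0 < m_instruments <= m_snps")
        if self.m_mediator_instruments < 0 or \
                self.m_instruments + self.m_mediator_instruments > self.m_snps:
            raise ValueError("m_instruments + m_mediator_instruments must fit in m_snps")
        for name in ("gamma_sd", "delta_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ValueError("palindromic_fraction must be in [0, 1]")

    @property
    def beta0(self) -> float:
        """Implied total exposure → outcome effect, theta + beta_em * beta_mo."""
        return self.theta_direct + self.beta_em * self.beta_mo

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class LdBlockSpec:
    """Block-diagonal AR(1) linkage disequilibrium.

    Within a block the SNP correlation is r(i, j) = rho^|i-j|; across blocks
    it is exactly 0 (blocks are placed on far-apart positions).  The implied
    correlation matrix is symmetric positive semi-definite with unit diagonal.
    """

    block_sizes: tuple[int, ...]
    rho: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")

    @property
    def m_snps(self) -> int:
        return int(sum(self.block_sizes))

    @classmethod
    def independent(cls, m_snps: int) -> "LdBlockSpec":
        return cls(block_sizes=(1,) * m_snps, rho=0.0)

    def block_index(self) -> np.ndarray:
        """Block id per SNP, and within-block offset."""
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)

    def offsets(self) -> np.ndarray:
        return np.concatenate([np.arange(b) for b in self.block_sizes])


def ld_matrix(ld: LdBlockSpec, snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Square r-squared matrix: rho^(2|i-j|) within a block, 0 across blocks."""
    m = ld.m_snps
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(m)]
    if len(snp_ids) != m:
        raise ValueError("snp_ids length must equal the number of SNPs in the spec")
    blocks = ld.block_index()
    offs = ld.offsets()
    same = blocks[:, None] == blocks[None, :]
    dist = np.abs(offs[:, None] - offs[None, :])
    with np.errstate(over="ignore"):
        r2 = np.where(same, (ld.rho ** 2) ** dist.astype(float), 0.0)
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=list(snp_ids), columns=list(snp_ids))


@dataclass
class TripletTruth:
    """Exactly-known per-SNP effects behind one simulated triplet."""

    per_snp: pd.DataFrame  # snp, gamma, delta, Gamma, alpha, instrument flags
    beta0: float
    scenario: CausalScenario

    def to_tsv(self, path) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False)


def _positions(ld: LdBlockSpec) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome labels and base-pair positions; blocks > 10,000 kb apart."""
    blocks = ld.block_index()
    offs = ld.offsets()
    chrom = (blocks % _N_CHROMS) + 1
    block_on_chrom = blocks // _N_CHROMS
    pos = 1 + block_on_chrom * _BLOCK_SPACING_BP + offs * _WITHIN_BLOCK_SPACING_BP
    return chrom.astype(str), pos.astype(np.int64)


def _alleles_and_eaf(rng, m, scenario: CausalScenario):
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, size=m)
    pal = rng.random(m) < scenario.palindromic_fraction
    if pal.any():
        if scenario.ambiguous_palindromes:
            maf[pal] = rng.uniform(0.45, 0.4999, size=int(pal.sum()))
        else:
            # keep palindromic frequencies informative so harmonization can succeed
            maf[pal] = rng.uniform(0.05, 0.35, size=int(pal.sum()))
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    pal_pick = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    non_pick = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    for i in range(m):
        ea[i], oa[i] = (_PALINDROMIC_PAIRS[pal_pick[i]] if pal[i]
                        else _NONPAL_PAIRS[non_pick[i]])
    mirror = rng.random(m) < 0.5
    eaf = np.where(mirror, 1.0 - maf, maf)
    return ea, oa, eaf, maf, pal


def _observe(rng, true_beta, maf, n) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    pval = np.clip(2.0 * sps.norm.sf(np.abs(beta) / se), 1e-320, 1.0)
    return beta, se, pval


def _assemble(trait_id, snp, chrom, pos, ea, oa, eaf, beta, se, pval, n) -> GwasSumStats:
    df = pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval,
        "n": pd.array([n] * len(snp), dtype="Int64"),
    })
    return GwasSumStats(trait_id, df[list(CANONICAL_COLUMNS)])


def simulate_triplet(
    scenario: CausalScenario,
    ld: LdBlockSpec | None = None,
    trait_prefix: str = "",
) -> tuple[GwasSumStats, GwasSumStats, GwasSumStats, TripletTruth]:
    """Simulate exposure, mediator and outcome summary statistics.

    The three traits share identical SNP ids, alleles and positions.  Returns
    the three :class:`GwasSumStats` plus a :class:`TripletTruth` carrying the
    per-SNP true effects and the implied total effect beta0.
    """
    if ld is None:
        ld = LdBlockSpec.independent(scenario.m_snps)
    if ld.m_snps != scenario.m_snps:
        raise ValueError("LD spec and scenario disagree on the number of SNPs")
    rng = np.random.default_rng(scenario.seed)
    m = scenario.m_snps

    snp = np.array([f"rs{i + 1}" for i in range(m)], dtype=object)
    chrom, pos = _positions(ld)
    ea, oa, eaf, maf, _pal = _alleles_and_eaf(rng, m, scenario)

    perm = rng.permutation(m)
    exp_idx = perm[: scenario.m_instruments]
    med_idx = perm[scenario.m_instruments:
                   scenario.m_instruments + scenario.m_mediator_instruments]
    is_exp = np.zeros(m, dtype=bool); is_exp[exp_idx] = True
    is_med = np.zeros(m, dtype=bool); is_med[med_idx] = True

    gamma = np.where(is_exp, rng.normal(0.0, scenario.gamma_sd, size=m), 0.0)
    d_own = np.where(is_med, rng.normal(0.0, scenario.delta_sd, size=m), 0.0)
    delta = scenario.beta_em * gamma + d_own
    alpha = (rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=m)
             if (scenario.pleiotropy_sd > 0 or scenario.pleiotropy_mean != 0)
             else np.zeros(m))
    Gamma = scenario.theta_direct * gamma + scenario.beta_mo * delta + alpha

    bx, sx, px = _observe(rng, gamma, maf, scenario.n_exposure)
    bm, sm, pm = _observe(rng, delta, maf, scenario.n_mediator)
    by, sy, py = _observe(rng, Gamma, maf, scenario.n_outcome)

    pre = trait_prefix
    exposure = _assemble(pre + "exposure", snp, chrom, pos, ea, oa, eaf,
                         bx, sx, px, scenario.n_exposure)
    mediator = _assemble(pre + "mediator", snp, chrom, pos, ea, oa, eaf,
                         bm, sm, pm, scenario.n_mediator)
    outcome = _assemble(pre + "outcome", snp, chrom, pos, ea, oa, eaf,
                        by, sy, py, scenario.n_outcome)

    truth = TripletTruth(
        per_snp=pd.DataFrame({
            "snp": snp, "gamma": gamma, "delta": delta, "Gamma": Gamma,
            "alpha": alpha,
            "exposure_instrument": is_exp, "mediator_instrument": is_med,
        }),
        beta0=scenario.beta0,
        scenario=scenario,
    )
    return exposure, mediator, outcome, truth


# ---------------------------------------------------------------------------
# Multi-trait planted screens
# ---------------------------------------------------------------------------

def _disjoint_block_positions(n_traits: int, m_per: int) -> tuple[np.ndarray, np.ndarray]:
    """One far-apart block of m_per SNPs per trait (no cross-trait LD)."""
    chrom = np.repeat((np.arange(n_traits) % _N_CHROMS) + 1, m_per).astype(str)
    block_on_chrom = np.repeat(np.arange(n_traits) // _N_CHROMS, m_per)
    offs = np.tile(np.arange(m_per), n_traits)
    pos = 1 + block_on_chrom * _BLOCK_SPACING_BP + offs * _WITHIN_BLOCK_SPACING_BP
    return chrom, pos.astype(np.int64)


def simulate_exposure_screen(
    effects: Sequence[float],
    m_instruments: int = 20,
    gamma_sd: float = 0.1,
    n_exposure: int = 50_000,
    n_outcome: int = 36_000,
    maf_range: tuple[float, float] = (0.05, 0.45),
    seed: int = 0,
) -> tuple[dict[str, GwasSumStats], GwasSumStats, pd.DataFrame]:
    """Many exposures against one outcome, with planted causal effects.

    Each exposure gets its own block of ``m_instruments`` independent SNPs;
    exposure i's true effect on the outcome is ``effects[i]`` (0 plants a null
    trait).  Returns ``(exposures, outcome, truth)`` where the outcome GWAS
    covers the union of all SNPs and ``truth`` records per-exposure effects.
    """
    rng = np.random.default_rng(seed)
    n_traits = len(effects)
    m_total = n_traits * m_instruments
    snp = np.array([f"rs{i + 1}" for i in range(m_total)], dtype=object)
    chrom, pos = _disjoint_block_positions(n_traits, m_instruments)
    lo, hi = maf_range
    maf = rng.uniform(lo, hi, size=m_total)
    pick = rng.integers(0, len(_NONPAL_PAIRS), size=m_total)
    ea = np.array([_NONPAL_PAIRS[p][0] for p in pick], dtype=object)
    oa = np.array([_NONPAL_PAIRS[p][1] for p in pick], dtype=object)
    eaf = maf.copy()

    owner = np.repeat(np.arange(n_traits), m_instruments)
    gamma = rng.normal(0.0, gamma_sd, size=m_total)
    Gamma = np.asarray(effects, dtype=float)[owner] * gamma

    exposures: dict[str, GwasSumStats] = {}
    for t in range(n_traits):
        mask = owner == t
        g = np.where(mask, gamma, 0.0)
        bx, sx, px = _observe(rng, g, maf, n_exposure)
        exposures[f"exposure{t + 1}"] = _assemble(
            f"exposure{t + 1}", snp, chrom, pos, ea, oa, eaf, bx, sx, px, n_exposure)
    by, sy, py = _observe(rng, Gamma, maf, n_outcome)
    outcome = _assemble("outcome", snp, chrom, pos, ea, oa, eaf, by, sy, py, n_outcome)

    truth = pd.DataFrame({
        "trait_id": [f"exposure{t + 1}" for t in range(n_traits)],
        "effect": list(effects),
    })
    return exposures, outcome, truth


def simulate_mediation_screen(
    n_exposures: int = 5,
    n_mediators: int = 3,
    planted: tuple[int, int] = (0, 0),
    theta_direct: float = 0.1,
    beta_em: float = 0.5,
    beta_mo: float = 0.4,
    m_instruments: int = 20,
    gamma_sd: float = 0.1,
    delta_sd: float = 0.15,
    n_exposure: int = 50_000,
    n_mediator: int = 5_000,
    n_outcome: int = 36_000,
    maf_range: tuple[float, float] = (0.05, 0.45),
    seed: int = 0,
):
    """Exposure x mediator x one-outcome grid with a single planted chain.

    Only exposure ``planted[0]`` affects the outcome (directly and through
    mediator ``planted[1]``); every other trait is null.  Each trait has its
    own disjoint block of instruments.  Mediator GWAS cover their own SNPs
    plus all exposure SNPs (so exposure → mediator legs are estimable).
    Returns ``(exposures, mediators, outcome, truth)``.
    """
    rng = np.random.default_rng(seed)
    ie, im = planted
    n_traits = n_exposures + n_mediators
    m_total = n_traits * m_instruments
    snp = np.array([f"rs{i + 1}" for i in range(m_total)], dtype=object)
    chrom, pos = _disjoint_block_positions(n_traits, m_instruments)
    maf = rng.uniform(*maf_range, size=m_total)
    pick = rng.integers(0, len(_NONPAL_PAIRS), size=m_total)
    ea = np.array([_NONPAL_PAIRS[p][0] for p in pick], dtype=object)
    oa = np.array([_NONPAL_PAIRS[p][1] for p in pick], dtype=object)
    eaf = maf.copy()

    owner = np.repeat(np.arange(n_traits), m_instruments)  # 0..nE-1 exposures, then mediators
    gamma_all = rng.normal(0.0, gamma_sd, size=m_total)     # raw per-SNP effect sizes
    d_all = rng.normal(0.0, delta_sd, size=m_total)

    exposures: dict[str, GwasSumStats] = {}
    for e in range(n_exposures):
        g = np.where(owner == e, gamma_all, 0.0)
        bx, sx, px = _observe(rng, g, maf, n_exposure)
        exposures[f"lipid{e + 1}"] = _assemble(
            f"lipid{e + 1}", snp, chrom, pos, ea, oa, eaf, bx, sx, px, n_exposure)

    mediators: dict[str, GwasSumStats] = {}
    med_true: dict[int, np.ndarray] = {}
    for mmi in range(n_mediators):
        own = owner == (n_exposures + mmi)
        d = np.where(own, d_all, 0.0)
        if mmi == im:  # planted: exposure ie raises this mediator
            d = d + np.where(owner == ie, beta_em * gamma_all, 0.0)
        med_true[mmi] = d
        bm, sm, pm = _observe(rng, d, maf, n_mediator)
        mediators[f"immune{mmi + 1}"] = _assemble(
            f"immune{mmi + 1}", snp, chrom, pos, ea, oa, eaf, bm, sm, pm, n_mediator)

    Gamma = np.where(owner == ie, theta_direct * gamma_all, 0.0) + beta_mo * med_true[im]
    by, sy, py = _observe(rng, Gamma, maf, n_outcome)
    outcome = _assemble("outcome", snp, chrom, pos, ea, oa, eaf, by, sy, py, n_outcome)

    truth = {
        "planted": (f"lipid{ie + 1}", f"immune{im + 1}", "outcome"),
        "beta0": theta_direct + beta_em * beta_mo,
        "theta_direct": theta_direct, "beta_em": beta_em, "beta_mo": beta_mo,
    }
    return exposures, mediators, outcome, truth
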