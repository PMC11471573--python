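"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized per-SNP pairs (beta_x, se_x, beta_y, se_y)
and return a :class:`MREstimate` carrying the causal estimate on the log-odds
scale together with its odds-ratio and 95% confidence-interval view.

* Wald ratio: beta_y / beta_x for a single instrument (first-order delta SE).
* IVW: weighted regression of beta_y on beta_x through the origin with
  weights 1/se_y^2; the fixed-effect SE is (sum w beta_x^2)^(-1/2), the
  multiplicative random-effects variant inflates it by
  sqrt(max(1, Q/(k-1))) where Q is Cochran's Q.
* Weighted median: the 50% crossing point of the inverse-variance-weighted
  ordered per-SNP ratio estimates; SE by seeded parametric bootstrap.
  Consistent when at least half the weight comes from valid instruments.
* MR-Egger: weighted regression *with* an unconstrained intercept after
  orienting all beta_x >= 0; the slope estimates the causal effect under the
  InSIDE assumption, the intercept the average directional pleiotropy.
  Coefficient SEs use multiplicative overdispersion but never shrink below
  the fixed-effect SEs; p-values from t with k-2 degrees of freedom.

Method dispatch follows the screening convention: with k >= 3 instruments
both IVW and the weighted median are reported, otherwise IVW alone (k = 1
degenerates to the Wald ratio); the Egger fit is reserved for sensitivity
analysis of traits with more than three instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedPair

__all__ = [
    "MREstimate", "EggerIntercept", "MRConfig", "Z95",
    "wald_ratio", "ivw", "weighted_median", "egger", "run_mr", "beta_to_or",
    "q_statistic",
]

#: 97.5% normal quantile used for 95% CIs (full precision for bit-stable round trips).
Z95 = 1.959964

_DEFAULT_WM_SEED = 20240930


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with odds-ratio reporting."""

    method: str          # wald_ratio | ivw_fe | ivw_mre | weighted_median | egger_slope
    beta: float
    se: float
    pval: float
    n_snps: int
    or_point: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        orp, lo, hi = beta_to_or(self.beta, self.se)
        object.__setattr__(self, "or_point", orp)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)


@dataclass(frozen=True)
class EggerIntercept:
    """The intercept row of an MR-Egger fit: average directional pleiotropy."""

    intercept: float
    se: float
    pval: float
    df: int


@dataclass(frozen=True)
class MRConfig:
    """Estimation settings for :func:`run_mr`."""

    ivw_variant: str = "multiplicative_random"   # or "fixed"
    k2_variant: str = "fixed"                    # Q has 1 df at k=2; overdispersion unstable
    n_boot: int = 1000
    seed: int = _DEFAULT_WM_SEED


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with 95% CI exp(beta -/+ 1.959964 * se)."""
    if se < 0:
        raise EstimationError("se must be >= 0")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def _arrays(pairs: Sequence[HarmonizedPair]):
    if not pairs:
        raise EstimationError("no harmonized pairs supplied")
    if any(p.dropped for p in pairs):
        raise EstimationError("dropped harmonized records must not reach estimators")
    bx = np.array([p.beta_x for p in pairs], dtype=float)
    sx = np.array([p.se_x for p in pairs], dtype=float)
    by = np.array([p.beta_y for p in pairs], dtype=float)
    sy = np.array([p.se_y for p in pairs], dtype=float)
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise EstimationError("standard errors must be positive")
    return bx, sx, by, sy


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * sps.norm.sf(abs(z)), 1e-320, 1.0))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument ratio estimate beta_y / beta_x (first-order SE)."""
    if pair.dropped:
        raise EstimationError("dropped harmonized records must not reach estimators")
    if pair.beta_x == 0:
        raise EstimationError(f"{pair.snp_id}: undefined ratio, exposure beta is 0")
    beta = pair.beta_y / pair.beta_x
    se = pair.se_y / abs(pair.beta_x)
    return MREstimate("wald_ratio", beta, se, _norm_p(beta / se), 1)


def q_statistic(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, int]:
    """Cochran's Q over per-SNP ratio estimates with weights bx^2/sy^2.

    Algebraically identical to the weighted residual sum of squares of the
    IVW origin regression; the single source of truth for both the
    heterogeneity test and the multiplicative random-effects inflation.
    """
    w = bx ** 2 / sy ** 2
    ratios = by / bx
    b_ivw = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - b_ivw) ** 2))
    return q, len(bx) - 1


def ivw(pairs: Sequence[HarmonizedPair], variant: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of beta_y on beta_x through the origin with
    weights 1/se_y^2.  ``variant="fixed"`` uses the fixed-effect SE;
    ``"multiplicative_random"`` (the screening default) inflates it by
    sqrt(max(1, Q/(k-1))).  k=1 collapses to the Wald ratio.
    """
    if variant not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown IVW variant {variant!r}")
    bx, sx, by, sy = _arrays(pairs)
    k = len(bx)
    if np.any(bx == 0):
        raise EstimationError("exposure beta of 0 gives an undefined ratio; filter first")
    if k == 1:
        wr = wald_ratio(pairs[0])
        return MREstimate("ivw_fe", wr.beta, wr.se, wr.pval, 1)
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by) / sxx)
    se = sxx ** -0.5
    method = "ivw_fe"
    if variant == "multiplicative_random":
        q, df = q_statistic(bx, by, sy)
        se *= math.sqrt(max(1.0, q / df))
        method = "ivw_mre"
    return MREstimate(method, beta, se, _norm_p(beta / se), k)


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: int = _DEFAULT_WM_SEED,
) -> MREstimate:
    """Weighted-median estimate over per-SNP Wald ratios (k >= 3).

    Ratios beta_y/beta_x carry normalized inverse-variance weights
    w_j = beta_x_j^2 / se_y_j^2.  With ratios sorted ascending and cumulative
    midpoints s_j = (sum_{i<=j} w_i) - w_j/2, the estimate linearly
    interpolates the sorted ratios at s = 1/2.  The SE is the standard
    deviation of the estimate under a seeded parametric bootstrap resampling
    (beta_x, beta_y) from Normal(observed, se^2).
    """
    if len(pairs) < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    # deterministic bootstrap irrespective of input order
    pairs = sorted(pairs, key=lambda p: p.snp_id)
    bx, sx, by, sy = _arrays(pairs)
    beta = _weighted_median_point(bx, by, sy)
    rng = np.random.default_rng(seed)
    k = len(bx)
    bx_star = bx + rng.standard_normal((n_boot, k)) * sx
    by_star = by + rng.standard_normal((n_boot, k)) * sy
    boots = _weighted_median_point_rows(bx_star, by_star, sy)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", float(beta), se, _norm_p(beta / se), k)


def _weighted_median_point(bx, by, sy) -> float:
    ratios = by / bx
    w = bx ** 2 / sy ** 2
    return _interp_median(ratios, w)


def _interp_median(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    ws = w[order] / np.sum(w)
    s = np.cumsum(ws) - ws / 2.0
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _weighted_median_point_rows(bx, by, sy) -> np.ndarray:
    """Row-wise weighted medians for the bootstrap (vectorised)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by / bx
        w = bx ** 2 / sy ** 2
    order = np.argsort(ratios, axis=1, kind="mergesort")
    r = np.take_along_axis(ratios, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    ws = ws / np.sum(ws, axis=1, keepdims=True)
    s = np.cumsum(ws, axis=1) - ws / 2.0
    out = np.empty(len(r))
    for i in range(len(r)):  # np.interp is 1-D; rows are short
        if 0.5 <= s[i, 0]:
            out[i] = r[i, 0]
        elif 0.5 >= s[i, -1]:
            out[i] = r[i, -1]
        else:
            out[i] = np.interp(0.5, s[i], r[i])
    return out


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression (k >= 3): slope = causal effect, intercept = pleiotropy.

    Pairs are first oriented so that every beta_x >= 0 (sign of both members
    flipped where needed); the intercept is only interpretable in that
    orientation.  Weighted (1/se_y^2) linear regression with intercept;
    coefficient SEs carry multiplicative overdispersion bounded below by the
    fixed-effect SEs; two-sided p-values from t(k-2).
    """
    bx, sx, by, sy = _arrays(pairs)
    k = len(bx)
    if k < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise EstimationError("all exposure betas identical: singular Egger design")
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    df = k - 2
    sigma2 = float(np.sum(w * resid ** 2) / df)
    cov_fixed = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov_fixed)) * math.sqrt(max(1.0, sigma2))
    tvals = coef / ses
    pvals = np.clip(2.0 * sps.t.sf(np.abs(tvals), df), 1e-320, 1.0)
    slope = MREstimate("egger_slope", float(coef[1]), float(ses[1]), float(pvals[1]), k)
    intercept = EggerIntercept(float(coef[0]), float(ses[0]), float(pvals[0]), df)
    return slope, intercept


def run_mr(pairs: Sequence[HarmonizedPair], config: MRConfig | None = None) -> list[MREstimate]:
    """Dispatch the primary estimators by instrument count.

    k = 1 -> Wald ratio reported as IVW; k = 2 -> IVW only; k >= 3 -> IVW and
    weighted median.  (Egger is a sensitivity analysis, see
    :mod:`mrscreen.sensitivity`.)
    """
    cfg = config or MRConfig()
    k = len(pairs)
    if k == 0:
        raise EstimationError("no harmonized pairs supplied")
    if k == 1:
        return [ivw(pairs, variant="fixed")]
    if k == 2:
        return [ivw(pairs, variant=cfg.k2_variant)]
    out = [ivw(pairs, variant=cfg.ivw_variant)]
    out.append(weighted_median(pairs, n_boot=cfg.n_boot, seed=cfg.seed))
    return out
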