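"""Heterogeneity and pleiotropy diagnostics, and the dual robustness gate.

Two diagnostics qualify a causal estimate:

* Cochran's Q over the per-SNP ratio estimates (weights beta_x^2/se_y^2,
  upper-tail chi-squared with k-1 df).  Q p-value > 0.05 indicates no
  detectable heterogeneity.  This Q is the same statistic that inflates the
  IVW multiplicative random-effects SE.
* The MR-Egger intercept: a non-zero intercept signals average directional
  pleiotropy.  The test is evaluated only for traits with more than three
  instruments (the fit is too fragile below that).

A result passes the robustness gate iff the Q p-value exceeds 0.05 and,
where evaluated, the Egger intercept p-value does too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .estimators import EggerIntercept, EstimationError, egger, q_statistic, _arrays
from .harmonize import HarmonizedPair

__all__ = [
    "SensitivityReport", "cochran_q", "egger_intercept_test",
    "robustness_gate", "sensitivity_report",
]

#: Minimum instrument count for the intercept test ("more than three IVs").
MIN_K_EGGER_INTERCEPT = 4


@dataclass(frozen=True)
class SensitivityReport:
    """Diagnostics for one exposure/outcome analysis.

    ``egger_intercept`` (and friends) are None when the intercept test was
    not evaluated (k <= 3 instruments).
    """

    q: float
    q_df: int
    q_pval: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    @property
    def egger_evaluated(self) -> bool:
        return self.egger_intercept_pval is not None

    @property
    def passes_gate(self) -> bool:
        return robustness_gate(self.q_pval, self.egger_intercept_pval)


def cochran_q(pairs: Sequence[HarmonizedPair]) -> tuple[float, int, float]:
    """(Q, df, upper-tail chi-squared p) over per-SNP ratio estimates; k >= 2."""
    bx, _sx, by, sy = _arrays(pairs)
    if len(bx) < 2:
        raise EstimationError("Cochran's Q is undefined for fewer than 2 instruments")
    q, df = q_statistic(bx, by, sy)
    return q, df, float(sps.chi2.sf(q, df))


def egger_intercept_test(pairs: Sequence[HarmonizedPair]) -> EggerIntercept | None:
    """Egger intercept (estimate, SE, t(k-2) p-value), or None when k <= 3."""
    if len(pairs) < MIN_K_EGGER_INTERCEPT:
        return None
    _slope, intercept = egger(pairs)
    return intercept


def robustness_gate(q_pval: float, egger_intercept_pval: float | None = None,
                    alpha: float = 0.05) -> bool:
    """True iff no detectable heterogeneity and no detectable pleiotropy.

    ``q_pval > alpha`` and, when the intercept test was evaluated,
    ``egger_intercept_pval > alpha``.
    """
    if not np.isfinite(q_pval):
        raise ValueError("q_pval must be a finite probability")
    ok = q_pval > alpha
    if egger_intercept_pval is not None:
        ok = ok and (egger_intercept_pval > alpha)
    return bool(ok)


def sensitivity_report(pairs: Sequence[HarmonizedPair]) -> SensitivityReport:
    """Full diagnostics bundle for one harmonized analysis (k >= 2)."""
    q, df, q_p = cochran_q(pairs)
    intercept = egger_intercept_test(pairs)
    if intercept is None:
        return SensitivityReport(q, df, q_p)
    return SensitivityReport(
        q, df, q_p,
        egger_intercept=intercept.intercept,
        egger_intercept_se=intercept.se,
        egger_intercept_pval=intercept.pval,
    )
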