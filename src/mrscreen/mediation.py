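"""Two-step MR mediation: effect decomposition along exposure→mediator→outcome.

Three univariable MR estimates are composed per triplet:

* beta0 — total exposure → outcome effect (exposure instruments);
* beta2 — exposure → mediator effect (exposure instruments);
* beta1 — mediator → outcome effect (the mediator's *own* instruments).

The indirect (mediated) effect is the coefficient product beta1 * beta2; the
direct effect is beta0 - beta1*beta2, so direct + indirect = beta0 holds as
an exact algebraic identity.  The proportion mediated,
100 * indirect / beta0, is reported only when the total and indirect effects
share sign — "inconsistent mediation", where the mediated path opposes the
total effect, has no meaningful proportion and is exported as NA.

beta1 comes from univariable mediator → outcome MR rather than multivariable
MR adjusting for the exposure; see the methods note for the caveat this
carries.  An optional first-order delta-method SE for the indirect effect is
provided as an extension (the decomposition itself is point-estimate based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .estimators import MRConfig, MREstimate, ivw
from .harmonize import analysis_ready, harmonize_pair
from .instruments import InstrumentSet, build_instrument_set
from .ld import LdProvider
from .sumstats import GwasSumStats

__all__ = [
    "MediationResult", "MissingInstrumentsError",
    "compute_indirect", "decompose", "indirect_se_delta",
    "run_mediation", "select_mediation_triplets",
]


class MissingInstrumentsError(ValueError):
    """A mediation leg has no eligible instruments; names the failing leg."""


@dataclass(frozen=True)
class MediationResult:
    """One exposure → mediator → outcome decomposition (one export row)."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta0: float                  # total exposure → outcome
    beta1: float                  # mediator → outcome
    beta2: float                  # exposure → mediator
    indirect: float               # beta1 * beta2
    direct: float                 # beta0 - indirect
    proportion_pct: float | None  # 100 * indirect / beta0, NA when inconsistent
    consistent: bool

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "total": self.beta0,
            "direct": self.direct,
            "indirect": self.indirect,
            "proportion_pct": float("nan") if self.proportion_pct is None
                              else self.proportion_pct,
        }


def compute_indirect(beta1: float, beta2: float) -> float:
    """Coefficient-product indirect effect, beta1 * beta2."""
    if not (math.isfinite(beta1) and math.isfinite(beta2)):
        raise ValueError("both coefficients must be finite")
    return beta1 * beta2


def decompose(beta0: float, indirect: float) -> tuple[float, float | None, bool]:
    """Split a total effect into (direct, proportion_pct, consistent).

    ``direct = beta0 - indirect`` always.  The mediated proportion
    ``100 * indirect / beta0`` is returned only when total and indirect are
    both nonzero and strictly share sign; otherwise None (exported "NA").
    """
    if not (math.isfinite(beta0) and math.isfinite(indirect)):
        raise ValueError("effects must be finite")
    direct = beta0 - indirect
    consistent = beta0 * indirect > 0
    proportion = 100.0 * indirect / beta0 if consistent else None
    return direct, proportion, consistent


def indirect_se_delta(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """First-order delta-method SE of the product beta1*beta2 (extension)."""
    return math.sqrt(beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2)


def _make_result(exposure_id, mediator_id, outcome_id,
                 beta0: float, beta1: float, beta2: float) -> MediationResult:
    indirect = compute_indirect(beta1, beta2)
    direct, proportion, consistent = decompose(beta0, indirect)
    return MediationResult(exposure_id, mediator_id, outcome_id,
                           beta0, beta1, beta2, indirect, direct,
                           proportion, consistent)


def _ivw_leg(iv: InstrumentSet, target: GwasSumStats, leg: str,
             eaf_halfwidth: float, cfg: MRConfig) -> MREstimate:
    if iv.is_empty:
        raise MissingInstrumentsError(f"no eligible instruments for the {leg} leg")
    pairs = analysis_ready(harmonize_pair(iv.as_sumstats(), target, eaf_halfwidth))
    if not pairs:
        raise MissingInstrumentsError(
            f"no instruments survive harmonization for the {leg} leg")
    return ivw(pairs, variant=cfg.ivw_variant if len(pairs) > 2 else "fixed")


def run_mediation(
    exposure: GwasSumStats,
    mediator: GwasSumStats,
    outcome: GwasSumStats,
    ld: LdProvider,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    f_threshold: float = 10.0,
    eaf_halfwidth: float = 0.08,
    config: MRConfig | None = None,
) -> MediationResult:
    """Full two-step MR for one triplet, from raw summary statistics.

    Instruments are selected independently for the exposure (used for the
    beta0 and beta2 legs) and for the mediator (beta1 leg); each leg is an
    IVW estimate on harmonized pairs.  Raises
    :class:`MissingInstrumentsError` naming the first leg without usable
    instruments.
    """
    cfg = config or MRConfig()
    iv_x = build_instrument_set(exposure, ld, p_threshold, r2_threshold,
                                window_kb, f_threshold)
    iv_m = build_instrument_set(mediator, ld, p_threshold, r2_threshold,
                                window_kb, f_threshold)
    beta0 = _ivw_leg(iv_x, outcome, "exposure→outcome", eaf_halfwidth, cfg)
    beta2 = _ivw_leg(iv_x, mediator, "exposure→mediator", eaf_halfwidth, cfg)
    beta1 = _ivw_leg(iv_m, outcome, "mediator→outcome", eaf_halfwidth, cfg)
    return _make_result(exposure.trait_id, mediator.trait_id, outcome.trait_id,
                        beta0.beta, beta1.beta, beta2.beta)


def select_mediation_triplets(
    exposure_outcome: pd.DataFrame,
    mediator_outcome: pd.DataFrame,
    exposure_mediator: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Candidate (exposure, mediator, outcome) triplets from three MR screens.

    Each input is an estimates table with at least the columns
    ``exposure, outcome, method, pval`` (only IVW rows are consulted for the
    three gates; weighted-median rows of the exposure→mediator screen drive
    the ``wm_significant`` annotation, the figure-style asterisk).  A triplet
    is a candidate iff all three IVW links have p < alpha.
    """
    def _ivw(df):
        return df[df["method"].str.startswith("ivw")]

    eo = _ivw(exposure_outcome)
    mo = _ivw(mediator_outcome)
    em = _ivw(exposure_mediator)
    wm = exposure_mediator[exposure_mediator["method"] == "weighted_median"]
    wm_p = {(r.exposure, r.outcome): r.pval for r in wm.itertuples(index=False)}

    rows = []
    for out_id in sorted(eo["outcome"].unique()):
        sig_exp = eo[(eo["outcome"] == out_id) & (eo["pval"] < alpha)]
        sig_med = mo[(mo["outcome"] == out_id) & (mo["pval"] < alpha)]
        for e in sig_exp.itertuples(index=False):
            for m in sig_med.itertuples(index=False):
                link = em[(em["exposure"] == e.exposure)
                          & (em["outcome"] == m.exposure)]
                if link.empty or link["pval"].iloc[0] >= alpha:
                    continue
                wmp = wm_p.get((e.exposure, m.exposure))
                rows.append({
                    "exposure": e.exposure,
                    "mediator": m.exposure,
                    "outcome": out_id,
                    "p_exposure_outcome": e.pval,
                    "p_mediator_outcome": m.pval,
                    "p_exposure_mediator": float(link["pval"].iloc[0]),
                    "wm_significant": bool(wmp is not None and wmp < alpha),
                })
    cols = ["exposure", "mediator", "outcome", "p_exposure_outcome",
            "p_mediator_outcome", "p_exposure_mediator", "wm_significant"]
    return pd.DataFrame(rows, columns=cols)
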