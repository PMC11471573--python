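"""Simulation-based calibration experiments for the pipeline.

Each function plants a known truth with the synthetic generator, runs the
estimation machinery exactly as a user would, and measures a frequentist
operating characteristic: confidence-interval coverage, null rejection rate,
mediation-proportion recovery, or planted-screen recovery.  They power the
acceptance checks and are handy for users who want to re-verify calibration
under their own scenarios.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimators import Z95, ivw
from .harmonize import analysis_ready, harmonize_pair
from .ld import IndependentLdProvider
from .mediation import MissingInstrumentsError, run_mediation
from .screen import ScreenConfig, run_screen
from .simulate import CausalScenario, simulate_exposure_screen, simulate_triplet

__all__ = [
    "COVERAGE_SCENARIO", "ivw_coverage", "ivw_null_rejection",
    "mediation_proportion_recovery", "planted_screen_recovery",
]

#: Estimator-calibration scenario: 30 instruments, every GWAS at n = 50,000.
COVERAGE_SCENARIO = CausalScenario(
    m_snps=30, m_instruments=30, m_mediator_instruments=0,
    n_exposure=50_000, n_mediator=50_000, n_outcome=50_000,
)


def _ivw_on_triplet(scenario: CausalScenario):
    exposure, _, outcome, truth = simulate_triplet(scenario)
    pairs = analysis_ready(harmonize_pair(exposure, outcome))
    return ivw(pairs), truth


def ivw_coverage(n_reps: int = 1000, seed: int = 0,
                 scenario: CausalScenario = COVERAGE_SCENARIO) -> float:
    """Fraction of replicates whose IVW 95% CI covers the true total effect.

    Uses the scenario's instrument SNPs directly (no selection step), so the
    number measures pure estimator calibration.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        scn = replace(scenario, seed=int(rng.integers(0, 2 ** 31 - 1)))
        est, truth = _ivw_on_triplet(scn)
        hits += est.beta - Z95 * est.se <= truth.beta0 <= est.beta + Z95 * est.se
    return hits / n_reps


def ivw_null_rejection(n_reps: int = 1000, seed: int = 0,
                       scenario: CausalScenario = COVERAGE_SCENARIO,
                       alpha: float = 0.05) -> float:
    """IVW p < alpha rate when the true total effect is exactly zero."""
    null = replace(scenario, theta_direct=0.0, beta_mo=0.0)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        scn = replace(null, seed=int(rng.integers(0, 2 ** 31 - 1)))
        est, _ = _ivw_on_triplet(scn)
        rejections += est.pval < alpha
    return rejections / n_reps


def mediation_proportion_recovery(n_reps: int = 500, seed: int = 0,
                                  scenario: CausalScenario | None = None) -> float:
    """Median estimated proportion mediated (%) over full-pipeline replicates.

    Default chain: theta_direct 0.1, beta_em 0.5, beta_mo 0.4, so the true
    proportion is 100 * 0.2 / 0.3 = 66.7%.  Every leg goes through instrument
    selection, harmonization and IVW, exactly like a real analysis.
    """
    base = scenario or CausalScenario()
    rng = np.random.default_rng(seed)
    ld = IndependentLdProvider()
    props = []
    while len(props) < n_reps:
        scn = replace(base, seed=int(rng.integers(0, 2 ** 31 - 1)))
        exposure, mediator, outcome, _ = simulate_triplet(scn)
        try:
            res = run_mediation(exposure, mediator, outcome, ld)
        except MissingInstrumentsError:  # vanishingly rare under the defaults
            continue
        if res.proportion_pct is not None:
            props.append(res.proportion_pct)
    return float(np.median(props))


def planted_screen_recovery(
    n_reps: int = 20, seed: int = 0,
    effects: tuple[float, ...] = (0.3, -0.25, 0.0, 0.0, 0.0, 0.0),
    alpha: float = 0.05,
) -> dict[str, float]:
    """Recovery and false-positive rates of the multi-exposure screen.

    Returns ``planted_recovery_rate`` (fraction of replicates in which every
    planted causal exposure is IVW-significant) and ``null_fp_rate`` (per-test
    false-positive rate over the pooled null exposures, expected ~ alpha).
    """
    rng = np.random.default_rng(seed)
    planted = {f"exposure{i + 1}" for i, e in enumerate(effects) if e != 0.0}
    nulls = {f"exposure{i + 1}" for i, e in enumerate(effects) if e == 0.0}
    recovered = fp = 0
    for _ in range(n_reps):
        s = int(rng.integers(0, 2 ** 31 - 1))
        exposures, outcome, _ = simulate_exposure_screen(list(effects), seed=s)
        res = run_screen(exposures, {"outcome": outcome},
                         IndependentLdProvider(),
                         ScreenConfig(seed=s, alpha=alpha))
        sig = set(res.significant["exposure"])
        recovered += planted <= sig
        fp += len(sig & nulls)
    return {
        "planted_recovery_rate": recovered / n_reps,
        "null_fp_rate": fp / (n_reps * len(nulls)),
    }
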