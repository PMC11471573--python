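"""Orchestrate the full screening workflow over many traits.

Pipeline per exposure/outcome pair: instrument selection → harmonization →
MR estimation (IVW, plus weighted median at k >= 3) → sensitivity
diagnostics.  Significance is declared at IVW p < alpha with no
multiple-testing correction by default (exploratory screening convention);
an optional Benjamini–Hochberg flag is available.  With mediator traits
supplied, candidate exposure → mediator → outcome triplets are selected from
the three screens and decomposed into total/direct/indirect effects.

Traits whose instrument sets come up empty are listed in an exclusions
report rather than silently skipped.  Given a config and seed the whole run
is deterministic, and the manifest echoes everything needed to reproduce it.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimators import EstimationError, MRConfig, MREstimate, run_mr
from .harmonize import analysis_ready, harmonize_pair
from .instruments import build_instrument_set
from .ld import LdProvider, MatrixLdProvider
from .mediation import MediationResult, _make_result, select_mediation_triplets
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import GwasSumStats, SumStatsError, read_sumstats

logger = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "ScreenResult", "run_screen", "run_screen_from_paths",
           "export_tables"]

_ESTIMATE_COLUMNS = ["exposure", "outcome", "method", "n_snps",
                     "beta", "se", "pval", "or", "ci_low", "ci_high"]
_SENSITIVITY_COLUMNS = ["exposure", "outcome", "egger_intercept",
                        "intercept_pval", "q", "q_pval", "passes_gate"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and settings for a screening run (echoed into the manifest)."""

    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    f_min: float = 10.0
    alpha: float = 0.05
    ivw_variant: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    eaf_halfwidth: float = 0.08
    bh_adjust: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_instrument <= 1) or not (0 < self.alpha < 1):
            raise ValueError("p_instrument and alpha must be probabilities")
        if self.clump_r2 < 0 or self.clump_window_kb <= 0 or self.f_min < 0:
            raise ValueError("invalid clumping/strength thresholds")

    def mr_config(self, pair_index: int = 0) -> MRConfig:
        # per-pair bootstrap seed derived deterministically from the run seed
        return MRConfig(ivw_variant=self.ivw_variant, n_boot=self.n_boot,
                        seed=(self.seed * 1_000_003 + pair_index) % (2 ** 31 - 1))


@dataclass
class ScreenResult:
    """Everything one screening run produced."""

    estimates: pd.DataFrame
    sensitivity: pd.DataFrame
    exclusions: pd.DataFrame
    significant: pd.DataFrame          # IVW-significant exposure/outcome pairs
    mediation: pd.DataFrame            # Table of decompositions (may be empty)
    triplets: pd.DataFrame             # candidate triplets with link p-values
    manifest: dict


def _estimate_row(exposure_id, outcome_id, est: MREstimate) -> dict:
    return {"exposure": exposure_id, "outcome": outcome_id, "method": est.method,
            "n_snps": est.n_snps, "beta": est.beta, "se": est.se, "pval": est.pval,
            "or": est.or_point, "ci_low": est.ci_low, "ci_high": est.ci_high}


def _sensitivity_row(exposure_id, outcome_id, rep: SensitivityReport) -> dict:
    return {"exposure": exposure_id, "outcome": outcome_id,
            "egger_intercept": rep.egger_intercept,
            "intercept_pval": rep.egger_intercept_pval,
            "q": rep.q, "q_pval": rep.q_pval, "passes_gate": rep.passes_gate}


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _screen_block(
    exposures: Mapping[str, GwasSumStats],
    outcomes: Mapping[str, GwasSumStats],
    ld: LdProvider,
    cfg: ScreenConfig,
    pair_counter: list[int],
    instrument_cache: dict,
    exclusion_rows: list[dict],
):
    """All exposure x outcome analyses for one block of the workflow."""
    est_rows, sens_rows = [], []
    for exp_id in sorted(exposures):
        if exp_id not in instrument_cache:
            iv = build_instrument_set(
                exposures[exp_id], ld, cfg.p_instrument, cfg.clump_r2,
                cfg.clump_window_kb, cfg.f_min)
            instrument_cache[exp_id] = iv
            if iv.is_empty:
                exclusion_rows.append({"trait_id": exp_id,
                                       "reason": "no eligible IVs"})
        iv = instrument_cache[exp_id]
        if iv.is_empty:
            continue
        for out_id in sorted(outcomes):
            pairs = analysis_ready(harmonize_pair(
                iv.as_sumstats(), outcomes[out_id], cfg.eaf_halfwidth))
            if not pairs:
                exclusion_rows.append({
                    "trait_id": exp_id,
                    "reason": f"no instruments shared with outcome {out_id}"})
                continue
            pair_counter[0] += 1
            try:
                ests = run_mr(pairs, cfg.mr_config(pair_counter[0]))
            except EstimationError as exc:
                exclusion_rows.append({"trait_id": exp_id,
                                       "reason": f"{out_id}: {exc}"})
                continue
            est_rows += [_estimate_row(exp_id, out_id, e) for e in ests]
            if len(pairs) >= 2:
                sens_rows.append(_sensitivity_row(exp_id, out_id,
                                                  sensitivity_report(pairs)))
    return est_rows, sens_rows


def run_screen(
    exposures: Mapping[str, GwasSumStats],
    outcomes: Mapping[str, GwasSumStats],
    ld: LdProvider,
    config: ScreenConfig | None = None,
    mediators: Mapping[str, GwasSumStats] | None = None,
) -> ScreenResult:
    """Run the whole screen (and mediation, when mediators are supplied).

    Deterministic given ``config.seed``.  Raises if no exposure/outcome pair
    is analyzable at all.
    """
    cfg = config or ScreenConfig()
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")
    cache: dict = {}
    exclusion_rows: list[dict] = []
    counter = [0]

    est_rows, sens_rows = _screen_block(exposures, outcomes, ld, cfg,
                                        counter, cache, exclusion_rows)
    estimates = pd.DataFrame(est_rows, columns=_ESTIMATE_COLUMNS)
    if estimates.empty:
        raise SumStatsError("zero analyzable exposure/outcome pairs")

    med_est = pd.DataFrame(columns=_ESTIMATE_COLUMNS)
    link_est = pd.DataFrame(columns=_ESTIMATE_COLUMNS)
    if mediators:
        mo_rows, mo_sens = _screen_block(mediators, outcomes, ld, cfg,
                                         counter, cache, exclusion_rows)
        med_est = pd.DataFrame(mo_rows, columns=_ESTIMATE_COLUMNS)
        sens_rows += mo_sens
        # exposure → mediator legs only for screened-significant exposures
        sig_exp = _significant(estimates, cfg)
        sig_med = _significant(med_est, cfg)
        exp_subset = {e: exposures[e] for e in sorted(set(sig_exp["exposure"]))}
        med_subset = {m: mediators[m] for m in sorted(set(sig_med["exposure"]))}
        if exp_subset and med_subset:
            em_rows, em_sens = _screen_block(
                exp_subset, {m: mediators[m] for m in med_subset}, ld, cfg,
                counter, cache, exclusion_rows)
            link_est = pd.DataFrame(em_rows, columns=_ESTIMATE_COLUMNS)
            sens_rows += em_sens

    sensitivity = pd.DataFrame(sens_rows, columns=_SENSITIVITY_COLUMNS)
    significant = _significant(estimates, cfg)

    triplets = pd.DataFrame()
    mediation_rows: list[dict] = []
    if mediators and not link_est.empty:
        triplets = select_mediation_triplets(estimates, med_est, link_est,
                                             alpha=cfg.alpha)
        all_est = pd.concat([estimates, med_est, link_est], ignore_index=True)
        ivw_rows = all_est[all_est["method"].str.startswith("ivw")]
        ivw_lookup = {(r.exposure, r.outcome): r.beta
                      for r in ivw_rows.itertuples(index=False)}
        for t in triplets.itertuples(index=False):
            res = _make_result(
                t.exposure, t.mediator, t.outcome,
                beta0=ivw_lookup[(t.exposure, t.outcome)],
                beta1=ivw_lookup[(t.mediator, t.outcome)],
                beta2=ivw_lookup[(t.exposure, t.mediator)],
            )
            row = res.to_row()
            row["wm_significant"] = t.wm_significant
            mediation_rows.append(row)
    mediation = pd.DataFrame(
        mediation_rows,
        columns=["exposure", "mediator", "outcome", "total", "direct",
                 "indirect", "proportion_pct", "wm_significant"])

    estimates_all = pd.concat(
        [estimates, med_est, link_est], ignore_index=True
    ) if mediators else estimates
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "mrscreen_version": __version__,
        "n_exposures": len(exposures),
        "n_mediators": len(mediators or {}),
        "n_outcomes": len(outcomes),
    }
    exclusions = pd.DataFrame(exclusion_rows, columns=["trait_id", "reason"])
    return ScreenResult(estimates_all, sensitivity, exclusions, significant,
                        mediation, triplets, manifest)


def _significant(estimates: pd.DataFrame, cfg: ScreenConfig) -> pd.DataFrame:
    ivw_rows = estimates[estimates["method"].str.startswith("ivw")].copy()
    if ivw_rows.empty:
        return ivw_rows
    if cfg.bh_adjust:
        ivw_rows["pval_adj"] = _bh(ivw_rows["pval"].to_numpy())
        return ivw_rows[ivw_rows["pval_adj"] < cfg.alpha].reset_index(drop=True)
    return ivw_rows[ivw_rows["pval"] < cfg.alpha].reset_index(drop=True)


def _load_traits(patterns: Sequence[str]) -> dict[str, GwasSumStats]:
    out: dict[str, GwasSumStats] = {}
    for pattern in patterns:
        matches = sorted(_glob.glob(str(pattern))) or [str(pattern)]
        for path in matches:
            try:
                stats = read_sumstats(path)
            except SumStatsError as exc:
                logger.error("skipping %s: %s", path, exc)
                continue
            out[stats.trait_id] = stats
    return out


def run_screen_from_paths(
    exposure_paths: Sequence[str],
    outcome_paths: Sequence[str],
    ld_matrix_path: str,
    mediator_paths: Sequence[str] | None = None,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Path/glob-driven wrapper around :func:`run_screen` (the CLI entry)."""
    exposures = _load_traits(exposure_paths)
    outcomes = _load_traits(outcome_paths)
    mediators = _load_traits(mediator_paths) if mediator_paths else None
    ld = MatrixLdProvider.from_tsv(ld_matrix_path)
    return run_screen(exposures, outcomes, ld, config, mediators)


def export_tables(result: ScreenResult, out_dir: str | Path) -> dict[str, Path]:
    """Write estimates/sensitivity/mediation/exclusions TSVs plus manifest.json.

    NA is rendered literally; re-export is idempotent and numeric columns
    round-trip at full repr precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("estimates", result.estimates),
                     ("sensitivity", result.sensitivity),
                     ("mediation", result.mediation),
                     ("exclusions", result.exclusions),
                     ("significant", result.significant),
                     ("triplets", result.triplets)]:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep="NA")
        paths[name] = p
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths
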