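"""End-to-end screen: planted-trait recovery, determinism, exports, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mrscreen.cli import main as cli_main
from mrscreen.ld import IndependentLdProvider
from mrscreen.screen import ScreenConfig, export_tables, run_screen
from mrscreen.simulate import (simulate_exposure_screen,
                               simulate_mediation_screen)
from mrscreen.sumstats import write_sumstats


EFFECTS = [0.3, -0.25, 0.0, 0.0, 0.0, 0.0]
PLANTED = {"exposure1", "exposure2"}


def _run(seed, config=None):
    exposures, outcome, _ = simulate_exposure_screen(EFFECTS, seed=seed)
    return run_screen(exposures, {"outcome": outcome}, IndependentLdProvider(),
                      config or ScreenConfig(seed=seed))


class TestExposureScreen:
    def test_planted_traits_always_recovered(self):
        for seed in range(5):
            sig = set(_run(seed).significant["exposure"])
            assert PLANTED <= sig, f"seed {seed}"

    def test_null_false_positive_rate_near_alpha(self):
        """Pooled over replicates, null exposures reach IVW p < 0.05 at ~5%."""
        fp = trials = 0
        for seed in range(15):
            sig = set(_run(seed).significant["exposure"])
            nulls = {f"exposure{i}" for i in range(3, 7)}
            fp += len(sig & nulls)
            trials += len(nulls)
        assert fp / trials < 0.18  # binomial(60, 0.05) upper bound

    def test_deterministic_byte_identical_exports(self, tmp_path):
        r1 = _run(3)
        r2 = _run(3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        export_tables(r1, d1)
        export_tables(r2, d2)
        for name in ("estimates.tsv", "sensitivity.tsv", "significant.tsv",
                     "exclusions.tsv", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_trait_without_instruments_lands_in_exclusions(self):
        exposures, outcome, _ = simulate_exposure_screen(EFFECTS, seed=1)
        # a trait with hopeless p-values everywhere
        dull = exposures["exposure1"].records.copy()
        dull["pval"] = 0.5
        from mrscreen.sumstats import GwasSumStats
        exposures["dull_trait"] = GwasSumStats("dull_trait", dull)
        res = run_screen(exposures, {"outcome": outcome},
                         IndependentLdProvider(), ScreenConfig(seed=1))
        assert "dull_trait" in set(res.exclusions["trait_id"])
        assert "dull_trait" not in set(res.estimates["exposure"])

    def test_estimates_round_trip_full_precision(self, tmp_path):
        res = _run(2)
        paths = export_tables(res, tmp_path)
        back = pd.read_csv(paths["estimates"], sep="\t",
                           float_precision="round_trip")
        np.testing.assert_array_equal(back["beta"].to_numpy(),
                                      res.estimates["beta"].to_numpy())
        np.testing.assert_array_equal(back["se"].to_numpy(),
                                      res.estimates["se"].to_numpy())

    def test_zero_analyzable_pairs_is_hard_error(self):
        exposures, outcome, _ = simulate_exposure_screen([0.0], m_instruments=3,
                                                         seed=0)
        weak = exposures["exposure1"].records.copy()
        weak["pval"] = 0.9
        from mrscreen.sumstats import GwasSumStats, SumStatsError
        with pytest.raises(SumStatsError):
            run_screen({"e": GwasSumStats("e", weak)}, {"outcome": outcome},
                       IndependentLdProvider(), ScreenConfig())


class TestMediationScreen:
    def test_planted_triplet_always_detected(self):
        for seed in range(4):
            exposures, mediators, outcome, truth = simulate_mediation_screen(
                seed=seed)
            res = run_screen(exposures, {"outcome": outcome},
                             IndependentLdProvider(), ScreenConfig(seed=seed),
                             mediators=mediators)
            trips = set(zip(res.triplets["exposure"], res.triplets["mediator"]))
            assert (truth["planted"][0], truth["planted"][1]) in trips
            assert not res.mediation.empty

    def test_false_triplets_rare(self):
        extras = 0
        for seed in range(6):
            exposures, mediators, outcome, truth = simulate_mediation_screen(
                seed=100 + seed)
            res = run_screen(exposures, {"outcome": outcome},
                             IndependentLdProvider(), ScreenConfig(seed=seed),
                             mediators=mediators)
            extras += max(0, len(res.triplets) - 1)
        assert extras <= 3

    def test_mediation_rows_satisfy_additivity(self):
        exposures, mediators, outcome, _ = simulate_mediation_screen(seed=5)
        res = run_screen(exposures, {"outcome": outcome},
                         IndependentLdProvider(), ScreenConfig(seed=5),
                         mediators=mediators)
        for row in res.mediation.itertuples(index=False):
            assert row.direct + row.indirect == pytest.approx(row.total,
                                                              abs=1e-12)


class TestCli:
    def test_simulate_then_mr_and_mediate(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--seed", "7",
                                     "--out", str(out_dir)])
        assert r.exit_code == 0, r.output
        for name in ("exposure.tsv", "mediator.tsv", "outcome.tsv",
                     "truth.tsv", "ld.tsv", "scenario.json"):
            assert (out_dir / name).exists()
        r = runner.invoke(cli_main, ["mr",
                                     "--exposure", str(out_dir / "exposure.tsv"),
                                     "--outcome", str(out_dir / "outcome.tsv"),
                                     "--ld", str(out_dir / "ld.tsv")])
        assert r.exit_code == 0, r.output
        assert "ivw" in r.output
        r = runner.invoke(cli_main, ["mediate",
                                     "--exposure", str(out_dir / "exposure.tsv"),
                                     "--mediator", str(out_dir / "mediator.tsv"),
                                     "--outcome", str(out_dir / "outcome.tsv"),
                                     "--ld", str(out_dir / "ld.tsv")])
        assert r.exit_code == 0, r.output
        assert "proportion_pct=" in r.output

    def test_screen_config_workflow(self, tmp_path):
        exposures, outcome, _ = simulate_exposure_screen(EFFECTS[:3], seed=4)
        data = tmp_path / "data"
        data.mkdir()
        for stats in exposures.values():
            write_sumstats(stats, data / f"{stats.trait_id}.tsv")
        write_sumstats(outcome, data / "outcome.tsv")
        snps = outcome.snp_ids
        ld = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
        ld.to_csv(data / "ld.tsv", sep="\t")
        cfg = {
            "exposures": [str(data / "exposure*.tsv")],
            "outcomes": [str(data / "outcome.tsv")],
            "ld_matrix": str(data / "ld.tsv"),
            "out_dir": str(tmp_path / "out"),
            "seed": 4,
        }
        import yaml
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        r = CliRunner().invoke(cli_main, ["screen", "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        payload = json.loads(r.output.strip().splitlines()[-1])
        assert payload["n_significant"] >= 2
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_bad_config_exits_2(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text("outcomes: [x]\nld_matrix: y\n")
        r = CliRunner().invoke(cli_main, ["screen", "--config", str(cfg_path)])
        assert r.exit_code == 2

    def test_missing_data_exits_3(self, tmp_path):
        bad = tmp_path / "empty.tsv"
        bad.write_text("snp\tchr\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n")
        ld = tmp_path / "ld.tsv"
        ld.write_text("\trs1\nrs1\t1.0\n")
        r = CliRunner().invoke(cli_main, ["mr", "--exposure", str(bad),
                                          "--outcome", str(bad),
                                          "--ld", str(ld)])
        assert r.exit_code == 3
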