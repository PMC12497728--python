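import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from bcrdyn import pipeline, synthetic
from bcrdyn.synthetic import CohortConfig, PlantedConfig, generate_cohort, tiny_config


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        cfg_a = tiny_config(5)
        cfg_b = tiny_config(5)
        rec_a, truth_a = generate_cohort(cfg_a)
        rec_b, truth_b = generate_cohort(cfg_b)
        pd.testing.assert_frame_equal(rec_a, rec_b)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_same_seed_gives_byte_identical_fixture(self, tmp_path):
        a = synthetic.write_fixture(tiny_config(9), tmp_path / "a")
        b = synthetic.write_fixture(tiny_config(9), tmp_path / "b")
        for pa, pb in zip(a["sample_paths"], b["sample_paths"]):
            assert filecmp.cmp(pa, pb, shallow=False)
        assert filecmp.cmp(a["truth_path"], b["truth_path"], shallow=False)

    def test_different_seeds_differ(self):
        rec_a, _ = generate_cohort(tiny_config(5))
        rec_b, _ = generate_cohort(tiny_config(6))
        assert not rec_a.equals(rec_b)


class TestCohortStructure:
    def test_sequence_totals_equal_configured_depth(self, tiny_cohort):
        records, _ = tiny_cohort
        cfg = tiny_config(7)
        records = records.copy()
        records["chain_group"] = np.where(records["locus"] == "IGH", "IGH", "IgKL")
        totals = records.groupby(
            ["animal_id", "timepoint_hr", "chain_group"])["duplicate_count"].sum()
        assert set(totals.unique()) == {cfg.depth["IGH"], cfg.depth["IgKL"]}

    def test_truth_rows_match_planted_count(self, tiny_cohort):
        _, truth = tiny_cohort
        cfg = tiny_config(7)
        assert len(truth) == cfg.planted.n_light + cfg.planted.n_heavy

    def test_planted_lineages_present_at_their_timepoints(self, tiny_cohort):
        _, truth = tiny_cohort
        for tp in (0, 48, 72):
            assert (truth[f"count_{tp}"] > 0).all()
        # non-persistent planted lineages vanish at one week
        gone = truth[~truth["persistent"]]
        assert (gone["count_168"] == 0).all()

    def test_lambda_bias_of_planted_light_lineages(self):
        cfg = CohortConfig(
            seed=13, n_animals=2, depth={"IGH": 2000, "IgKL": 2000},
            n_lineages={"IGH": 100, "IgKL": 150},
            n_transient={"IGH": 50, "IgKL": 50},
            planted=PlantedConfig(n_light=40, n_heavy=4, baseline_frequency=1e-3),
        )
        _, truth = generate_cohort(cfg)
        light = truth[truth["chain_group"] == "IgKL"]
        lam = (light["locus"] == "IGL").mean()
        # binomial(40, 0.8): 3 sigma is about 0.19
        assert lam == pytest.approx(cfg.planted.lambda_bias, abs=0.2)

    def test_infeasible_config_rejected(self):
        cfg = tiny_config(1)
        cfg.planted = PlantedConfig(n_light=10_000)
        with pytest.raises(ValueError):
            generate_cohort(cfg)

    def test_null_cohort_has_empty_truth(self):
        _, truth = generate_cohort(tiny_config(3, planted=False))
        assert truth.empty


class TestDistributionalFidelity:
    def test_realized_frequency_fold_changes_near_target(self, tiny_pipeline):
        """Planted 48 h frequency fold changes scatter around the configured
        target with multinomial noise."""
        truth = tiny_pipeline["truth"]
        res = tiny_pipeline["result"]
        matched = synthetic.match_truth_to_lineages(truth, res.summary)
        fc = tiny_pipeline["fold_changes"]
        freq48 = fc[(fc["index"] == "frequency") & (fc["timepoint_hr"] == 48)]
        planted_fc = freq48[freq48["lineage_id"].isin(matched["lineage_id"])]
        target = tiny_config(7).planted.log2_fc_frequency
        assert abs(np.median(planted_fc["log2_fc"]) - target) < 0.3

    def test_rank_abundance_slope_matches_configured_exponent(self):
        cfg = CohortConfig(seed=3, n_animals=1, planted=None)
        records, _ = generate_cohort(cfg)
        light0 = records[(records["timepoint_hr"] == 0) & (records["locus"] != "IGH")]
        counts = (
            light0.groupby(["v_call", "j_call", "cdr3_aa"])["duplicate_count"]
            .sum().sort_values(ascending=False).to_numpy()
        )
        ranks = np.arange(5, 300)
        slope = np.polyfit(np.log(ranks), np.log(counts[4:299]), 1)[0]
        assert abs(-slope - cfg.powerlaw_alpha) < 0.1 * cfg.powerlaw_alpha

    def test_mutation_rate_histogram_is_trimodal(self, tiny_cohort):
        """Per-sequence rates pile up at the three configured peaks with
        valleys in between (naive near zero, intermediate, memory-like)."""
        records, _ = tiny_cohort
        light = records[(records["locus"] != "IGH") & (records["timepoint_hr"] == 0)]
        rates = (
            100.0 * (light["v_mismatches"] + light["j_mismatches"])
            / (light["v_aligned_len"] + light["j_aligned_len"])
        ).repeat(light["duplicate_count"])
        bands = [0.0, 0.5, 1.0, 2.5, 4.0, 10.0]
        hist, _ = np.histogram(rates, bands)
        naive, valley1, mid, valley2, memory = hist
        assert naive > valley1 and mid > valley1
        assert mid > valley2 and memory > valley2


def test_config_echo_round_trips_as_json(tmp_path):
    info = synthetic.write_fixture(
        CohortConfig(seed=2, n_animals=1, depth={"IGH": 300, "IgKL": 300},
                     n_lineages={"IGH": 20, "IgKL": 30},
                     n_transient={"IGH": 5, "IgKL": 5}, planted=None),
        tmp_path,
    )
    echoed = json.loads(info["config_path"].read_text())
    assert echoed["seed"] == 2
    assert echoed["n_animals"] == 1


def test_end_to_end_recovery_on_tiny_cohort(tiny_pipeline):
    """The pipeline finds every planted lineage in the tiny fixture and calls
    few extras (tiny depth tolerates a couple of sampling flukes)."""
    ev = pipeline.evaluate_calls(
        tiny_pipeline["calls"], tiny_pipeline["result"].summary,
        tiny_pipeline["truth"])
    assert ev["recall"] >= 0.95
    assert ev["precision"] >= 0.80
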