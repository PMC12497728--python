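import numpy as np
import pandas as pd
import pytest

from bcrdyn import pipeline, synthetic
from bcrdyn.dynamics import (
    classify_increased_decreased,
    constant_lineages,
    fold_changes,
    identify_expanded,
    kappa_lambda_lineage_ratio,
    original_expanded,
    sample_control_lineages,
)


def metrics_frame(rows):
    base = dict(animal_id="M1", chain_group="IgKL", lineage_id="L1",
                unique_cdr3=1, mutation_rate=1.0)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestFoldChanges:
    def test_eightfold_frequency_increase(self):
        m = metrics_frame(
            [{"timepoint_hr": 0, "cum_frequency": 5e-6},
             {"timepoint_hr": 48, "cum_frequency": 4e-5}]
        )
        fc = fold_changes(m)
        row = fc[(fc["index"] == "frequency") & (fc["timepoint_hr"] == 48)].iloc[0]
        assert row["log2_fc"] == pytest.approx(3.0, abs=1e-9)

    def test_equal_values_give_zero(self):
        m = metrics_frame(
            [{"timepoint_hr": 0, "cum_frequency": 1e-4},
             {"timepoint_hr": 72, "cum_frequency": 1e-4}]
        )
        fc = fold_changes(m)
        assert fc[fc["index"] == "frequency"]["log2_fc"].iloc[0] == 0.0

    def test_three_over_one_example(self):
        m = metrics_frame(
            [{"timepoint_hr": 0, "cum_frequency": 1e-5},
             {"timepoint_hr": 48, "cum_frequency": 3e-5}]
        )
        fc = fold_changes(m)
        row = fc[(fc["index"] == "frequency") & (fc["timepoint_hr"] == 48)].iloc[0]
        assert row["log2_fc"] == pytest.approx(np.log2(3), abs=1e-9)

    def test_zero_at_either_endpoint_is_undefined(self):
        m = metrics_frame(
            [
                {"timepoint_hr": 0, "cum_frequency": 0.0, "unique_cdr3": 0,
                 "mutation_rate": np.nan},
                {"timepoint_hr": 48, "cum_frequency": 1e-4},
                {"lineage_id": "L2", "timepoint_hr": 0, "cum_frequency": 1e-4},
                # L2 absent at 48 h entirely
            ]
        )
        fc = fold_changes(m)
        assert fc[fc["lineage_id"] == "L1"]["log2_fc"].isna().all()
        l2_48 = fc[(fc["lineage_id"] == "L2") & (fc["timepoint_hr"] == 48)]
        assert l2_48["log2_fc"].isna().all()


class TestIncreasedDecreased:
    @pytest.mark.parametrize(
        "log2_fc,expected",
        [(1.5, "increased"), (-2.0, "decreased"), (0.5, "neither"),
         (1.0, "neither"), (-1.0, "neither"), (np.nan, "neither")],
    )
    def test_default_symmetric_rule(self, log2_fc, expected):
        fc = pd.DataFrame([{"log2_fc": log2_fc}])
        assert classify_increased_decreased(fc)["status"].iloc[0] == expected

    def test_literal_decreased_rule_flags_mild_changes_decreased(self):
        fc = pd.DataFrame([{"log2_fc": 0.4}])
        assert classify_increased_decreased(fc)["status"].iloc[0] == "neither"
        out = classify_increased_decreased(fc, literal_decreased=True)
        assert out["status"].iloc[0] == "decreased"

    def test_no_lineage_both_increased_and_decreased(self, tiny_pipeline):
        fc = tiny_pipeline["fold_changes"]
        per_cell = fc.groupby(
            ["animal_id", "chain_group", "lineage_id", "index", "timepoint_hr"]
        )["status"].nunique()
        assert (per_cell == 1).all()


class TestIdentifyExpanded:
    def _fc(self, rows):
        base = dict(animal_id="M1", chain_group="IgKL", lineage_id="L1")
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_frequency_criterion_pair(self):
        fc = self._fc(
            [{"index": "frequency", "timepoint_hr": 48, "log2_fc": 3.5,
              "post_value": 2e-5, "baseline_value": 2e-6}]
        )
        calls = identify_expanded(fc)
        assert calls["expanded"].iloc[0]
        assert calls["criteria_met"].iloc[0] == "frequency"
        assert calls["trigger_timepoint"].iloc[0] == 48

    def test_below_thresholds_not_expanded(self):
        fc = self._fc(
            [{"index": "frequency", "timepoint_hr": 48, "log2_fc": 2.9,
              "post_value": 2e-5, "baseline_value": 3e-6},
             {"index": "unique_cdr3", "timepoint_hr": 72, "log2_fc": 1.9,
              "post_value": 30, "baseline_value": 8}]
        )
        assert not identify_expanded(fc)["expanded"].iloc[0]

    def test_mutation_rate_only_at_72h(self):
        fc = self._fc(
            [{"index": "mutation_rate", "timepoint_hr": 72, "log2_fc": 1.4,
              "post_value": 7.0, "baseline_value": 2.7},
             {"index": "frequency", "timepoint_hr": 72, "log2_fc": 0.2,
              "post_value": 1e-4, "baseline_value": 9e-5}]
        )
        calls = identify_expanded(fc)
        assert calls["expanded"].iloc[0]
        assert calls["criteria_met"].iloc[0] == "mutation_rate"

    def test_absolute_threshold_must_hold_at_same_timepoint(self):
        fc = self._fc(
            [{"index": "frequency", "timepoint_hr": 48, "log2_fc": 3.5,
              "post_value": 5e-6, "baseline_value": 5e-7}]  # 0.0005% < 0.001%
        )
        assert not identify_expanded(fc)["expanded"].iloc[0]

    def test_heavy_chain_has_no_unique_cdr3_criterion(self):
        fc = self._fc(
            [{"chain_group": "IGH", "index": "unique_cdr3", "timepoint_hr": 48,
              "log2_fc": 5.0, "post_value": 100, "baseline_value": 3}]
        )
        assert not identify_expanded(fc)["expanded"].iloc[0]

    def test_every_expanded_lineage_is_increased_somewhere(self, tiny_pipeline):
        """Threshold nesting: expansion thresholds all exceed the increased
        threshold of 1, so expanded implies increased on >= 1 index."""
        fc, calls = tiny_pipeline["fold_changes"], tiny_pipeline["calls"]
        expanded = calls[calls["expanded"]]
        inc = fc[fc["status"] == "increased"]
        inc_keys = set(zip(inc["animal_id"], inc["chain_group"], inc["lineage_id"]))
        for _, row in expanded.iterrows():
            assert (row["animal_id"], row["chain_group"], row["lineage_id"]) in inc_keys


class TestConstantLineages:
    def test_present_at_all_timepoints(self):
        rows = [{"timepoint_hr": tp, "cum_frequency": 1e-4} for tp in
                (0, 8, 24, 48, 72, 168)]
        m = metrics_frame(rows)
        constant, pct = constant_lineages({"L1"}, m)
        assert constant == {"L1"} and pct == 100.0

    def test_absent_at_one_timepoint_not_constant(self):
        rows = [{"timepoint_hr": tp, "cum_frequency": 1e-4} for tp in
                (0, 24, 48, 72, 168)]  # missing 8 h
        constant, pct = constant_lineages({"L1"}, metrics_frame(rows))
        assert constant == set() and pct == 0.0

    def test_recovers_planted_persistence(self, tiny_pipeline):
        """Persistent planted lineages are constant; non-persistent ones are
        forced out at 1 week by construction."""
        res, truth = tiny_pipeline["result"], tiny_pipeline["truth"]
        calls = tiny_pipeline["calls"]
        matched = synthetic.match_truth_to_lineages(truth, res.summary)
        expanded_ids = set(calls.loc[calls["expanded"], "lineage_id"])
        constant, _ = constant_lineages(expanded_ids, res.metrics)
        for _, row in matched.iterrows():
            if row["lineage_id"] in expanded_ids:
                assert (row["lineage_id"] in constant) == bool(row["persistent"])


class TestOriginalExpanded:
    def test_baseline_members_and_exclusion_count(self, tiny_pipeline):
        res, calls = tiny_pipeline["result"], tiny_pipeline["calls"]
        records = pipeline.assign_lineages_to_records(
            tiny_pipeline["records"], res.clonotypes)
        expanded_ids = set(calls.loc[calls["expanded"], "lineage_id"])
        origin, n_excluded = original_expanded(records, expanded_ids)
        assert (origin["timepoint_hr"] == 0).all()
        assert set(origin["lineage_id"]) <= expanded_ids
        assert n_excluded == len(expanded_ids) - origin["lineage_id"].nunique()


class TestControlSampling:
    def _summary(self, n_kappa, n_lambda, rng):
        rows = []
        for i in range(n_kappa + n_lambda):
            locus = "IGK" if i < n_kappa else "IGL"
            rows.append(
                dict(lineage_id=f"P{i}", v_gene=f"{locus}V{i % 7 + 1}",
                     total_frequency=float(10 ** rng.uniform(-5, -2)))
            )
        return pd.DataFrame(rows)

    def test_count_and_ratio_mode_exact(self, rng):
        pool = self._summary(60, 40, rng)
        ref = self._summary(2, 8, rng)
        ref["lineage_id"] = [f"R{i}" for i in range(10)]
        ctl = sample_control_lineages(pool, ref, "match_kl_ratio_and_count", seed=0)
        assert len(ctl) == 10
        assert (ctl["v_gene"].str[:3] == "IGK").sum() == 2

    def test_frequency_mode_matches_bin_profile(self, rng):
        pool = self._summary(300, 200, rng)
        ref = self._summary(5, 5, rng)
        ref["lineage_id"] = [f"R{i}" for i in range(10)]
        ctl = sample_control_lineages(
            pool, ref, "match_frequency_distribution", seed=0)
        assert len(ctl) == 10
        edges = np.logspace(-5, -2, 11)
        ref_hist = np.histogram(ref["total_frequency"], edges)[0]
        ctl_hist = np.histogram(ctl["total_frequency"], edges)[0]
        # same coarse profile (allow one borderline bin shift)
        assert np.abs(ref_hist - ctl_hist).sum() <= 2

    def test_two_seeds_differ_but_profiles_agree(self, rng):
        pool = self._summary(300, 200, rng)
        ref = self._summary(5, 5, rng)
        ref["lineage_id"] = [f"R{i}" for i in range(10)]
        a = sample_control_lineages(pool, ref, "match_frequency_distribution", seed=1)
        b = sample_control_lineages(pool, ref, "match_frequency_distribution", seed=2)
        assert set(a["lineage_id"]) != set(b["lineage_id"])
        assert len(a) == len(b)

    def test_pool_must_exclude_reference(self, rng):
        pool = self._summary(5, 5, rng)
        with pytest.raises(ValueError):
            sample_control_lineages(pool, pool, "match_kl_ratio_and_count", seed=0)


def test_kappa_lambda_lineage_ratio():
    df = pd.DataFrame({"v_gene": ["IGKV1", "IGKV2", "IGKV3", "IGLV1"]})
    assert kappa_lambda_lineage_ratio(df) == 3.0
    with pytest.raises(ZeroDivisionError):
        kappa_lambda_lineage_ratio(pd.DataFrame({"v_gene": ["IGKV1"]}))
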