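"""End-to-end orchestration: records -> clonotypes -> lineages -> expansion calls.

These functions glue the per-module operations into the standard longitudinal
analysis and are what the command-line interface, the analysis drivers, and the
acceptance checks run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import diversity, mutation
from .dynamics import (
    classify_increased_decreased,
    fold_changes,
    identify_expanded,
    original_expanded,
)
from .lineage import cluster_lineages, lineage_metrics, lineage_summary
from .repertoire import prepare_records
from .synthetic import match_truth_to_lineages

SAMPLE_KEY = ["animal_id", "timepoint_hr", "chain_group"]
CLONO_KEY = ["animal_id", "chain_group", "v_gene", "j_gene", "cdr3_aa"]


def clonotype_timepoint_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample clonotype table across the whole cohort.

    One row per (animal, timepoint, chain group, V, J, CDR3) with summed
    duplicate counts, within-chain-group frequency, and pooled mutation sums.
    """
    df = records if "chain_group" in records.columns else prepare_records(records)
    w = df["duplicate_count"]
    out = (
        df.assign(
            _vmm=df["v_mismatches"] * w,
            _jmm=df["j_mismatches"] * w,
            _vlen=df["v_aligned_len"] * w,
            _jlen=df["j_aligned_len"] * w,
        )
        .groupby(CLONO_KEY + ["timepoint_hr"], sort=True)
        .agg(
            count=("duplicate_count", "sum"),
            mm_sum_v=("_vmm", "sum"),
            mm_sum_j=("_jmm", "sum"),
            len_sum_v=("_vlen", "sum"),
            len_sum_j=("_jlen", "sum"),
        )
        .reset_index()
    )
    totals = out.groupby(SAMPLE_KEY)["count"].transform("sum")
    out["frequency"] = out["count"] / totals
    return out


@dataclass
class PipelineResult:
    clonotypes: pd.DataFrame  # clonotype x timepoint rows with lineage_id
    metrics: pd.DataFrame     # lineage x timepoint metrics
    summary: pd.DataFrame     # one row per lineage


def run_lineage_pipeline(records: pd.DataFrame) -> PipelineResult:
    """Cluster lineages per animal (timepoints pooled) and compute metrics."""
    ct = clonotype_timepoint_table(records)
    ct = cluster_lineages(ct)
    return PipelineResult(
        clonotypes=ct,
        metrics=lineage_metrics(ct),
        summary=lineage_summary(ct),
    )


def call_expansions(metrics: pd.DataFrame, literal_decreased: bool = False):
    """Fold changes, increased/decreased statuses, and expansion calls."""
    fc = fold_changes(metrics)
    fc = classify_increased_decreased(fc, literal_decreased=literal_decreased)
    calls = identify_expanded(fc)
    return fc, calls


def assign_lineages_to_records(
    records: pd.DataFrame, clonotypes_with_lineage: pd.DataFrame
) -> pd.DataFrame:
    """Annotate raw records with the lineage_id of their clonotype."""
    df = records if "chain_group" in records.columns else prepare_records(records)
    mapping = clonotypes_with_lineage[CLONO_KEY + ["lineage_id"]].drop_duplicates()
    return df.merge(mapping, on=CLONO_KEY, how="left")


def evaluate_calls(
    calls: pd.DataFrame, summary: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Recall/precision of expansion calls against planted ground truth."""
    matched = match_truth_to_lineages(truth, summary)
    truth_keys = set(
        zip(matched["animal_id"], matched["chain_group"], matched["lineage_id"])
    )
    expanded = calls[calls["expanded"]]
    call_keys = set(
        zip(expanded["animal_id"], expanded["chain_group"], expanded["lineage_id"])
    )
    tp = len(truth_keys & call_keys)
    return {
        "n_planted": len(truth),
        "n_expanded_calls": len(call_keys),
        "true_positives": tp,
        "recall": tp / len(truth) if len(truth) else float("nan"),
        "precision": tp / len(call_keys) if call_keys else float("nan"),
        "matched_truth": matched,
    }


def mean_timepoint_overlap(
    metrics: pd.DataFrame, subset: set | None = None, method: str = "overlap"
) -> float:
    """Mean lineage overlap index over all timepoint pairs and animals.

    ``subset`` restricts the lineage universe (e.g. to expanded lineages).
    Pairs where either timepoint has no qualifying lineage are skipped.
    """
    from .similarity import timepoint_overlap

    values = []
    present = metrics[metrics["unique_cdr3"] >= 1]
    if subset is not None:
        present = present[present["lineage_id"].isin(subset)]
    for _, grp in present.groupby(["animal_id", "chain_group"]):
        by_tp = {
            tp: set(g["lineage_id"]) for tp, g in grp.groupby("timepoint_hr")
        }
        for t1, t2 in combinations(sorted(by_tp), 2):
            if by_tp[t1] and by_tp[t2]:
                values.append(timepoint_overlap(by_tp[t1], by_tp[t2], method=method))
    return float(np.mean(values)) if values else float("nan")


def origin_class_fractions(
    records_with_lineage: pd.DataFrame, lineage_ids, baseline_tp: int = 0
) -> pd.DataFrame:
    """Mutation-class fractions of a lineage set's baseline (0 hr) members."""
    origin, _ = original_expanded(records_with_lineage, lineage_ids, baseline_tp)
    if origin.empty:
        return pd.DataFrame(columns=["chain_group", "mutation_class", "fraction"])
    return mutation.class_proportions(origin)


def sample_diversity_table(records: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Clonotype-level Shannon/Gini/Top-N per (animal, timepoint, chain group)."""
    ct = clonotype_timepoint_table(records)
    rows = []
    for (animal, tp, cg), grp in ct.groupby(SAMPLE_KEY):
        freqs = grp["frequency"].to_numpy()
        rows.append(
            {
                "animal_id": animal,
                "timepoint_hr": tp,
                "chain_group": cg,
                "n_clonotypes": len(grp),
                "shannon": diversity.shannon_index(freqs),
                "gini": diversity.gini_index(freqs),
                f"top{top_n}": diversity.top_n_cumulative(freqs, top_n),
            }
        )
    return pd.DataFrame(rows)


def lineage_diversity_table(metrics: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Lineage-level Shannon/Gini/Top-N per sample (lineages in place of clonotypes)."""
    rows = []
    for (animal, tp, cg), grp in metrics.groupby(
        ["animal_id", "timepoint_hr", "chain_group"]
    ):
        freqs = grp.loc[grp["cum_frequency"] > 0, "cum_frequency"].to_numpy()
        if len(freqs) == 0:
            continue
        freqs = freqs / freqs.sum()
        rows.append(
            {
                "animal_id": animal,
                "timepoint_hr": tp,
                "chain_group": cg,
                "n_lineages": len(freqs),
                "shannon": diversity.shannon_index(freqs),
                "gini": diversity.gini_index(freqs),
                f"top{top_n}": diversity.top_n_cumulative(freqs, top_n),
            }
        )
    return pd.DataFrame(rows)


def increased_decreased_counts(fc_with_status: pd.DataFrame) -> pd.DataFrame:
    """Counts of increased and decreased lineages per animal/timepoint/index."""
    counts = (
        fc_with_status.groupby(
            ["animal_id", "chain_group", "timepoint_hr", "index", "status"]
        )["lineage_id"]
        .count()
        .unstack("status", fill_value=0)
        .reset_index()
    )
    for col in ("increased", "decreased"):
        if col not in counts.columns:
            counts[col] = 0
    return counts
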