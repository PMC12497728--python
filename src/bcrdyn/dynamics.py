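"""Longitudinal lineage dynamics: fold changes, expansion calls, controls.

For every lineage three indices are tracked per timepoint — cumulative
frequency, unique CDR3 count, and mean (pooled) mutation rate — and compared to
the pre-stimulation baseline (0 hr) as log2 fold changes.  A lineage is

* *increased* on an index when log2(FC) > 1,
* *decreased* when FC < 0.5 (log2(FC) < −1) under the default symmetric
  interpretation (the literal threshold log2(FC) < 0.5 is available
  behind ``literal_decreased=True``),
* *expanded* when, at 48 h or 72 h, at least one chain-specific criterion pair
  holds: a log2(FC) threshold together with an absolute threshold on the
  post-stimulation value at the same timepoint.

Lineages absent (or with a zero/undefined index) at either endpoint of a
comparison have an undefined fold change on that index and never contribute
calls on it.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

INDICES = ("frequency", "unique_cdr3", "mutation_rate")
TRIGGER_TIMEPOINTS = (48, 72)

#: Chain-specific expansion criteria: index -> (log2 FC threshold, absolute
#: threshold on the post-stimulation value).  Frequencies are fractions, so
#: 0.001% = 1e-5; mutation rates are percent.
EXPANSION_THRESHOLDS = {
    "IgKL": {
        "frequency": (3.0, 1e-5),
        "unique_cdr3": (2.0, 5.0),
        "mutation_rate": (1.3, 6.0),
    },
    "IGH": {
        "frequency": (3.0, 1e-5),
        "mutation_rate": (1.5, 5.0),
    },
}

_METRIC_COLS = {"frequency": "cum_frequency", "unique_cdr3": "unique_cdr3",
                "mutation_rate": "mutation_rate"}

LINEAGE_KEY = ["animal_id", "chain_group", "lineage_id"]


def fold_changes(metrics: pd.DataFrame, baseline_tp: int = 0) -> pd.DataFrame:
    """Per-lineage, per-index, per-timepoint log2 fold changes vs baseline.

    ``metrics`` is the long table from :func:`bcrdyn.lineage.lineage_metrics`;
    absent (lineage, timepoint) cells are treated as frequency 0 / unique 0 /
    mutation rate undefined.  Output columns: index, timepoint_hr,
    baseline_value, post_value, log2_fc.

    A fold change is defined only when both endpoints are positive: log2 of a
    zero ratio is undefined, so lineages unobserved (or with a zero index) at
    either the baseline or the post timepoint get log2_fc = NaN on that index
    and are never classified from it.  This keeps increased and decreased
    calls exactly symmetric under exchange of the two timepoints, which the
    repertoire-homeostasis null argument relies on.
    """
    long = metrics.melt(
        id_vars=LINEAGE_KEY + ["timepoint_hr"],
        value_vars=list(_METRIC_COLS.values()),
        var_name="index",
        value_name="value",
    )
    inv = {v: k for k, v in _METRIC_COLS.items()}
    long["index"] = long["index"].map(inv)

    base = (
        long[long["timepoint_hr"] == baseline_tp]
        .rename(columns={"value": "baseline_value"})
        .drop(columns="timepoint_hr")
    )
    post = long[long["timepoint_hr"] != baseline_tp].rename(columns={"value": "post_value"})
    fc = post.merge(base, on=LINEAGE_KEY + ["index"], how="left")

    # Absent timepoints: frequency and unique_cdr3 are true zeros, mutation
    # rate is undefined rather than zero.
    is_mut = fc["index"] == "mutation_rate"
    fc.loc[~is_mut, "post_value"] = fc.loc[~is_mut, "post_value"].fillna(0.0)
    fc.loc[~is_mut, "baseline_value"] = fc.loc[~is_mut, "baseline_value"].fillna(0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fc["post_value"] / fc["baseline_value"]
        fc["log2_fc"] = np.log2(ratio)
    undefined = ~(fc["baseline_value"] > 0) | ~(fc["post_value"] > 0)
    fc.loc[undefined, "log2_fc"] = np.nan
    return fc


def classify_increased_decreased(
    fold_change_table: pd.DataFrame, literal_decreased: bool = False
) -> pd.DataFrame:
    """Add a per-(index, timepoint) status column: increased/decreased/neither.

    Increased: log2(FC) > 1.  Decreased: log2(FC) < −1 by default (fold change
    below 0.5); with ``literal_decreased=True`` the literal reading
    log2(FC) < 0.5 is applied instead.  Undefined fold changes are ``neither``.
    """
    fc = fold_change_table.copy()
    dec_cut = 0.5 if literal_decreased else -1.0
    status = pd.Series("neither", index=fc.index, dtype=object)
    status[fc["log2_fc"] > 1.0] = "increased"
    status[fc["log2_fc"] < dec_cut] = "decreased"
    status[fc["log2_fc"].isna()] = "neither"
    fc["status"] = status
    return fc


def identify_expanded(
    fold_change_table: pd.DataFrame,
    thresholds: dict | None = None,
    trigger_timepoints: tuple[int, ...] = TRIGGER_TIMEPOINTS,
) -> pd.DataFrame:
    """Call stimulation-induced expanded lineages.

    A lineage is expanded when at 48 h or 72 h at least one criterion pair of
    its chain group holds: log2(FC) above the FC threshold AND the
    post-stimulation value above the absolute threshold, both at the same
    timepoint.  Returns one row per lineage with ``expanded``, the sorted
    ``criteria_met`` (comma-joined), ``n_criteria``, and the earliest
    ``trigger_timepoint`` (NaN when not expanded).
    """
    thresholds = thresholds or EXPANSION_THRESHOLDS
    fc = fold_change_table[fold_change_table["timepoint_hr"].isin(trigger_timepoints)].copy()

    def _hit(row):
        crit = thresholds.get(row["chain_group"], {}).get(row["index"])
        if crit is None or not np.isfinite(row["log2_fc"]):
            return False
        fc_thr, abs_thr = crit
        return row["log2_fc"] > fc_thr and row["post_value"] > abs_thr

    fc["hit"] = [
        _hit(row)
        for row in fc[["chain_group", "index", "log2_fc", "post_value"]].to_dict("records")
    ]

    hits = fc[fc["hit"]]
    calls = (
        fc[LINEAGE_KEY].drop_duplicates().set_index(LINEAGE_KEY).sort_index()
    )
    calls["expanded"] = False
    calls["criteria_met"] = ""
    calls["n_criteria"] = 0
    calls["trigger_timepoint"] = np.nan
    if not hits.empty:
        agg = hits.groupby(LINEAGE_KEY).agg(
            criteria_met=("index", lambda s: ",".join(sorted(set(s)))),
            n_criteria=("index", "nunique"),
            trigger_timepoint=("timepoint_hr", "min"),
        )
        calls.loc[agg.index, "expanded"] = True
        calls.loc[agg.index, ["criteria_met", "n_criteria", "trigger_timepoint"]] = agg
    return calls.reset_index()


def constant_lineages(
    expanded_ids, metrics: pd.DataFrame, timepoints=(0, 8, 24, 48, 72, 168)
) -> tuple[set, float]:
    """Expanded lineages observed (unique CDR3 >= 1) at every timepoint.

    Returns the constant subset and the percentage of constant lineages among
    the expanded set.
    """
    expanded_ids = set(expanded_ids)
    if not expanded_ids:
        return set(), float("nan")
    present = metrics[
        metrics["lineage_id"].isin(expanded_ids) & (metrics["unique_cdr3"] >= 1)
    ]
    n_tp = present.groupby("lineage_id")["timepoint_hr"].nunique()
    constant = set(n_tp[n_tp >= len(timepoints)].index)
    return constant, 100.0 * len(constant) / len(expanded_ids)


def original_expanded(
    records_with_lineage: pd.DataFrame, expanded_ids, baseline_tp: int = 0
) -> tuple[pd.DataFrame, int]:
    """Baseline (0 hr) members of expanded lineages — the origin view.

    Returns the 0 hr records of expanded lineages plus the number of expanded
    lineages excluded because they have no baseline members.
    """
    expanded_ids = set(expanded_ids)
    sub = records_with_lineage[records_with_lineage["lineage_id"].isin(expanded_ids)]
    origin = sub[sub["timepoint_hr"] == baseline_tp].copy()
    n_excluded = len(expanded_ids) - origin["lineage_id"].nunique()
    return origin, n_excluded


def lineage_locus(v_gene: pd.Series) -> pd.Series:
    """Locus of a light-chain lineage from its V-gene prefix (IGKV... -> IGK)."""
    return v_gene.str[:3]


def kappa_lambda_lineage_ratio(lineage_table: pd.DataFrame) -> float:
    """Ratio of kappa to lambda lineage counts in a lineage set."""
    locus = lineage_locus(lineage_table["v_gene"])
    k = int((locus == "IGK").sum())
    l = int((locus == "IGL").sum())
    if l == 0:
        raise ZeroDivisionError("kappa/lambda lineage ratio undefined: no lambda lineages")
    return k / l


def sample_control_lineages(
    pool: pd.DataFrame,
    reference: pd.DataFrame,
    mode: str,
    seed: int,
    frequency_col: str = "total_frequency",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Draw a control lineage set matched to a reference (expanded) set.

    ``mode='match_frequency_distribution'``: stratified draw over ``n_bins``
    log10-spaced frequency bins spanning the pool's nonzero range, so the
    control per-bin counts equal the reference's (nearest-bin fallback with a
    warning when a stratum is exhausted).

    ``mode='match_kl_ratio_and_count'``: same number of lineages as the
    reference with identical kappa:lambda lineage counts.

    The pool must not contain reference lineages.
    """
    import warnings

    rng = np.random.default_rng(seed)
    overlap = set(pool["lineage_id"]) & set(reference["lineage_id"])
    if overlap:
        raise ValueError("pool must exclude the reference lineages")

    if mode == "match_kl_ratio_and_count":
        picks = []
        pool_locus = lineage_locus(pool["v_gene"])
        ref_locus = lineage_locus(reference["v_gene"])
        for locus, n_needed in ref_locus.value_counts().items():
            candidates = pool.index[pool_locus == locus].to_numpy()
            if len(candidates) < n_needed:
                raise ValueError(f"pool too small for locus {locus}")
            picks.append(rng.choice(candidates, size=n_needed, replace=False))
        return pool.loc[np.concatenate(picks)].copy()

    if mode != "match_frequency_distribution":
        raise ValueError(f"unknown control-sampling mode {mode!r}")

    pool_f = pool[frequency_col].to_numpy(dtype=float)
    ref_f = reference[frequency_col].to_numpy(dtype=float)
    lo = max(min(pool_f[pool_f > 0].min(), ref_f[ref_f > 0].min()), 1e-12)
    hi = max(pool_f.max(), ref_f.max())
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[0], edges[-1] = 0.0, np.inf
    pool_bin = np.digitize(pool_f, edges) - 1
    ref_bin = np.digitize(ref_f, edges) - 1

    picks = []
    available = {b: list(np.flatnonzero(pool_bin == b)) for b in range(n_bins)}
    for b in range(n_bins):
        rng.shuffle(available[b])
    for b, n_needed in zip(*np.unique(ref_bin, return_counts=True)):
        got = 0
        for dist in range(n_bins):
            for bb in ({b} if dist == 0 else {b - dist, b + dist}):
                if 0 <= bb < n_bins:
                    while available[bb] and got < n_needed:
                        picks.append(available[bb].pop())
                        got += 1
            if got >= n_needed:
                break
            if dist == 1:
                warnings.warn(
                    f"frequency bin {b} exhausted; borrowing from neighbouring bins"
                )
        if got < n_needed:
            raise ValueError("pool too small to match the reference frequency profile")
    return pool.iloc[picks].copy()


def expansion_report(calls: pd.DataFrame) -> dict:
    """Summary counts per category and per criterion-overlap cell."""
    expanded = calls[calls["expanded"]]
    overlap_cells = (
        expanded.groupby("criteria_met")["lineage_id"].count().to_dict()
        if not expanded.empty
        else {}
    )
    multi = int((expanded["n_criteria"] >= 2).sum())
    return {
        "n_lineages_tested": int(len(calls)),
        "n_expanded": int(len(expanded)),
        "pct_multi_criteria": (100.0 * multi / len(expanded)) if len(expanded) else None,
        "criteria_overlap": overlap_cells,
    }


def write_expansion_report(calls: pd.DataFrame, tsv_path, json_path) -> None:
    calls.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(expansion_report(calls), fh, indent=2)
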