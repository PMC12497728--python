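"""Somatic hypermutation rates and mutation/isotype class partitioning.

The SHM rate of a set of sequences is the pooled ratio
``100 × (Σ v_i + Σ j_i) / (Σ V_i + Σ J_i)`` where v/j are V- and J-region
mismatch counts and V/J the aligned region lengths — not the mean of
per-sequence rates.  Class thresholds are strict inequalities; boundary values
fall into the intermediate/other classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_airr import chain_group

# Percent thresholds separating naive-like, intermediate, and memory/effector-like
# sequences.  Light chains: non-mutated < 0.5%, mutated > 4%.  Heavy chains:
# IgM/IgD non-mutated < 0.5%, IgA/G/E mutated > 3%, IgM mutated > 3%.
LIGHT_NONMUTATED_MAX = 0.5
LIGHT_MUTATED_MIN = 4.0
HEAVY_NONMUTATED_MAX = 0.5
HEAVY_MUTATED_MIN = 3.0

LIGHT_CLASSES = ("IgKL_nonmutated", "IgKL_intermediate", "IgKL_mutated")
HEAVY_CLASSES = ("IgMD_nonmutated", "IgAGE_mutated", "IgM_mutated", "other")


def shm_rate(records: pd.DataFrame, weighted: bool = True) -> float:
    """Pooled somatic hypermutation rate (percent) over a set of records.

    With ``weighted=True`` each record contributes ``duplicate_count`` copies
    to the pooled sums, i.e. every physical sequence is counted once.
    """
    if records.empty:
        raise ValueError("SHM rate undefined for an empty record set")
    w = records["duplicate_count"].to_numpy() if weighted else 1
    num = (records["v_mismatches"].to_numpy() * w).sum() + (
        records["j_mismatches"].to_numpy() * w
    ).sum()
    den = (records["v_aligned_len"].to_numpy() * w).sum() + (
        records["j_aligned_len"].to_numpy() * w
    ).sum()
    if den <= 0:
        raise ValueError("SHM rate undefined: zero total aligned length")
    return 100.0 * float(num) / float(den)


def per_record_rates(records: pd.DataFrame) -> pd.Series:
    """Per-sequence SHM rate in percent."""
    num = records["v_mismatches"] + records["j_mismatches"]
    den = records["v_aligned_len"] + records["j_aligned_len"]
    return 100.0 * num / den


def classify_mutation(records: pd.DataFrame) -> pd.Series:
    """Assign each record its mutation class label.

    Heavy chain: IgM/IgD with rate < 0.5% -> IgMD_nonmutated; IgA/IgG/IgE with
    rate > 3% -> IgAGE_mutated; IgM with rate > 3% -> IgM_mutated; else other.
    Light chain: rate < 0.5% -> IgKL_nonmutated; rate > 4% -> IgKL_mutated;
    else IgKL_intermediate.
    """
    rate = per_record_rates(records)
    heavy = records["locus"] == "IGH"
    iso = records["isotype"]

    label = pd.Series("other", index=records.index, dtype=object)

    light = ~heavy
    label[light] = "IgKL_intermediate"
    label[light & (rate < LIGHT_NONMUTATED_MAX)] = "IgKL_nonmutated"
    label[light & (rate > LIGHT_MUTATED_MIN)] = "IgKL_mutated"

    md = iso.isin(["IgM", "IgD"])
    age = iso.isin(["IgA", "IgG", "IgE"])
    label[heavy & md & (rate < HEAVY_NONMUTATED_MAX)] = "IgMD_nonmutated"
    label[heavy & age & (rate > HEAVY_MUTATED_MIN)] = "IgAGE_mutated"
    label[heavy & (iso == "IgM") & (rate > HEAVY_MUTATED_MIN)] = "IgM_mutated"
    return label


def class_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Duplicate-count-weighted mutation-class fractions per chain group.

    Returns a long table (chain_group, mutation_class, fraction); fractions sum
    to 1 within each chain group present in the sample.
    """
    if records.empty:
        raise ValueError("class proportions undefined for an empty sample")
    df = records.copy()
    if "chain_group" not in df.columns:
        df["chain_group"] = chain_group(df["locus"])
    df["mutation_class"] = classify_mutation(df)
    counts = (
        df.groupby(["chain_group", "mutation_class"], sort=True)["duplicate_count"]
        .sum()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("chain_group")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
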