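"""Clonotype aggregation, subsampling, gene usage, and the kappa/lambda ratio.

A clonotype is the unit of repertoire counting: the unique combination of V
gene, J gene, and CDR3 amino-acid sequence within a chain group.  Frequencies
are fractions in [0, 1], normalised within each (sample, chain group), where
the chain groups are IGH alone and IGK+IGL pooled ("IgKL").
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .io_airr import RepertoireSample, chain_group

_ALLELE_RE = re.compile(r"\*.*$")


def strip_allele(gene: str) -> str:
    """Drop an IMGT-style allele suffix: ``IGHV3-23*01`` -> ``IGHV3-23``."""
    return _ALLELE_RE.sub("", gene)


def _as_records(sample) -> pd.DataFrame:
    if isinstance(sample, RepertoireSample):
        return sample.records
    return sample


def prepare_records(records: pd.DataFrame, strip_alleles: bool = True) -> pd.DataFrame:
    """Annotate raw records with chain_group and allele-stripped gene calls."""
    out = records.copy()
    out["chain_group"] = chain_group(out["locus"])
    if strip_alleles:
        out["v_gene"] = out["v_call"].map(strip_allele)
        out["j_gene"] = out["j_call"].map(strip_allele)
    else:
        out["v_gene"] = out["v_call"]
        out["j_gene"] = out["j_call"]
    return out


CLONOTYPE_KEY = ["chain_group", "v_gene", "j_gene", "cdr3_aa"]


def build_clonotypes(sample, strip_alleles: bool = True) -> pd.DataFrame:
    """Aggregate records of one sample into clonotypes.

    Returns one row per unique (chain_group, v_gene, j_gene, cdr3_aa) with
    summed ``duplicate_count``, frequency within the chain group, the pooled
    mutation-rate numerator/denominator sums, the count-weighted mean mutation
    rate (percent), nucleotide-variant count, and (for IGH) isotype counts.
    """
    df = _as_records(sample)
    if df.empty:
        return pd.DataFrame(columns=CLONOTYPE_KEY + ["count", "frequency"])
    if "chain_group" not in df.columns:
        df = prepare_records(df, strip_alleles=strip_alleles)

    w = df["duplicate_count"]
    agg = df.assign(
        _vmm=df["v_mismatches"] * w,
        _jmm=df["j_mismatches"] * w,
        _vlen=df["v_aligned_len"] * w,
        _jlen=df["j_aligned_len"] * w,
    ).groupby(CLONOTYPE_KEY, sort=True)

    clono = agg.agg(
        count=("duplicate_count", "sum"),
        mm_sum_v=("_vmm", "sum"),
        mm_sum_j=("_jmm", "sum"),
        len_sum_v=("_vlen", "sum"),
        len_sum_j=("_jlen", "sum"),
        n_cdr3_nt=("cdr3", "nunique"),
    ).reset_index()

    totals = clono.groupby("chain_group")["count"].transform("sum")
    clono["frequency"] = clono["count"] / totals
    clono["mean_mutation_rate"] = (
        100.0
        * (clono["mm_sum_v"] + clono["mm_sum_j"])
        / (clono["len_sum_v"] + clono["len_sum_j"])
    )

    heavy = df[df["chain_group"] == "IGH"]
    if not heavy.empty:
        iso = (
            heavy.groupby(CLONOTYPE_KEY)
            .apply(
                lambda g: dict(g.groupby("isotype")["duplicate_count"].sum()),
                include_groups=False,
            )
            .rename("isotype_counts")
        )
        clono = clono.merge(iso, on=CLONOTYPE_KEY, how="left")
    else:
        clono["isotype_counts"] = None
    return clono


def subsample(sample: RepertoireSample, n: int, seed: int) -> RepertoireSample:
    """Draw exactly ``min(n, total_count)`` sequences without replacement.

    The draw is multivariate hypergeometric over the duplicate-count-expanded
    multiset of records, so every physical sequence copy is equally likely.
    Records drawn zero times are dropped; duplicate counts are re-aggregated.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    total = sample.total_count
    if n >= total:
        return sample
    rng = np.random.default_rng(seed)
    counts = sample.records["duplicate_count"].to_numpy()
    drawn = rng.multivariate_hypergeometric(counts, n, method="marginals")
    keep = drawn > 0
    records = sample.records[keep].copy()
    records["duplicate_count"] = drawn[keep]
    return RepertoireSample(
        animal_id=sample.animal_id,
        species=sample.species,
        timepoint_hr=sample.timepoint_hr,
        records=records.reset_index(drop=True),
    )


def gene_usage(records, level: str = "V", weight: str = "duplicate_count") -> pd.Series:
    """Sequence-weighted gene (or V-J pair) usage frequencies, summing to 1.

    ``records`` should already be restricted to one chain group (the
    normalisation is over whatever rows are passed in).
    """
    df = _as_records(records)
    if df.empty:
        raise ValueError("gene_usage requires a non-empty sample")
    if "v_gene" not in df.columns:
        df = prepare_records(df)
    if level == "V":
        keys = df["v_gene"]
    elif level == "J":
        keys = df["j_gene"]
    elif level == "VJ":
        keys = df["v_gene"] + "|" + df["j_gene"]
    else:
        raise ValueError(f"level must be V, J or VJ, got {level!r}")
    counts = df.groupby(keys)[weight].sum().sort_index()
    return counts / counts.sum()


def kappa_lambda_ratio(records) -> float:
    """Summed duplicate counts of IGK records over IGL records."""
    df = _as_records(records)
    k = df.loc[df["locus"] == "IGK", "duplicate_count"].sum()
    l = df.loc[df["locus"] == "IGL", "duplicate_count"].sum()
    if l == 0:
        raise ZeroDivisionError("kappa/lambda ratio undefined: no lambda sequences")
    return float(k) / float(l)
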