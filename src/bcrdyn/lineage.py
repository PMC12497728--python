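"""Clonal-lineage clustering and per-timepoint lineage metrics.

A lineage is a set of clonotypes from one animal (all timepoints pooled) that
share the V gene, J gene, and CDR3 length, and whose CDR3 amino-acid sequences
are connected under single linkage with Hamming distance <= 1.  Two CDR3s two
mismatches apart therefore co-cluster when an intermediate one-mismatch
sequence links them.  Lineage IDs are content-derived (hash of the sorted
member set) and hence deterministic.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict

import numpy as np
import pandas as pd

LINEAGE_GROUP_KEY = ["animal_id", "chain_group", "v_gene", "j_gene"]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            if rj < ri:  # keep the smallest index as root for determinism
                ri, rj = rj, ri
            self.parent[rj] = ri


def _components_within_bucket(cdr3s: list[str]) -> list[int]:
    """Single-linkage components under Hamming distance <= 1 on equal-length CDR3s.

    Uses the masked-position trick: two distinct equal-length strings are at
    Hamming distance 1 iff they agree after masking exactly one position, so
    hashing each string's L masked variants finds all distance-1 pairs in
    O(n·L) without the all-pairs scan.
    """
    uf = _UnionFind(len(cdr3s))
    buckets: dict[tuple[int, str], int] = {}
    for idx, s in enumerate(cdr3s):
        for pos in range(len(s)):
            key = (pos, s[:pos] + s[pos + 1:])
            first = buckets.setdefault(key, idx)
            if first != idx:
                uf.union(first, idx)
    return [uf.find(i) for i in range(len(cdr3s))]


def lineage_id_for(members: list[str], context: str) -> str:
    """Deterministic lineage identifier from the sorted member CDR3 set."""
    payload = context + "|" + "|".join(sorted(members))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def cluster_lineages(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Assign a ``lineage_id`` to every clonotype row.

    ``clonotypes`` needs columns animal_id, chain_group, v_gene, j_gene,
    cdr3_aa (duplicate rows across timepoints are fine; clustering operates on
    the unique keys).  Returns the input with a ``lineage_id`` column added.
    """
    keys = clonotypes[LINEAGE_GROUP_KEY + ["cdr3_aa"]].drop_duplicates()
    keys["cdr3_len"] = keys["cdr3_aa"].str.len()

    assignments = []
    for group_vals, grp in keys.groupby(LINEAGE_GROUP_KEY + ["cdr3_len"], sort=True):
        cdr3s = sorted(grp["cdr3_aa"].tolist())
        roots = _components_within_bucket(cdr3s)
        members_by_root: dict[int, list[str]] = defaultdict(list)
        for cdr3, root in zip(cdr3s, roots):
            members_by_root[root].append(cdr3)
        context = "|".join(str(v) for v in group_vals[:-1])
        lid_by_cdr3 = {}
        for root, members in members_by_root.items():
            lid = lineage_id_for(members, context)
            for cdr3 in members:
                lid_by_cdr3[cdr3] = lid
        sub = grp[LINEAGE_GROUP_KEY + ["cdr3_aa"]].copy()
        sub["lineage_id"] = sub["cdr3_aa"].map(lid_by_cdr3)
        assignments.append(sub)

    mapping = pd.concat(assignments, ignore_index=True)
    return clonotypes.merge(mapping, on=LINEAGE_GROUP_KEY + ["cdr3_aa"], how="left")


def lineage_metrics(clonotypes_by_timepoint: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage, per-timepoint metrics.

    Input: clonotype rows carrying ``lineage_id``, ``timepoint_hr``,
    ``frequency`` (within sample chain group) and the pooled mutation sums
    ``mm_sum_v/mm_sum_j/len_sum_v/len_sum_j``.

    Output columns: cum_frequency (sum of member clonotype frequencies),
    unique_cdr3 (distinct member CDR3-aa observed), mutation_rate (pooled SHM
    percent; NaN where the lineage is absent).  Only observed
    (lineage, timepoint) cells are returned; absence means metrics (0, 0, NaN).
    """
    grouped = clonotypes_by_timepoint.groupby(
        ["animal_id", "chain_group", "lineage_id", "timepoint_hr"], sort=True
    )
    out = grouped.agg(
        cum_frequency=("frequency", "sum"),
        unique_cdr3=("cdr3_aa", "nunique"),
        mm_v=("mm_sum_v", "sum"),
        mm_j=("mm_sum_j", "sum"),
        len_v=("len_sum_v", "sum"),
        len_j=("len_sum_j", "sum"),
    ).reset_index()
    out["mutation_rate"] = 100.0 * (out["mm_v"] + out["mm_j"]) / (out["len_v"] + out["len_j"])
    return out.drop(columns=["mm_v", "mm_j", "len_v", "len_j"])


def lineage_summary(clonotypes_with_lineage: pd.DataFrame) -> pd.DataFrame:
    """One row per lineage: genes, CDR3 length, member CDR3 set, total count."""
    grouped = clonotypes_with_lineage.groupby(
        LINEAGE_GROUP_KEY + ["lineage_id"], sort=True
    )
    out = grouped.agg(
        cdr3_set=("cdr3_aa", lambda s: tuple(sorted(set(s)))),
        total_count=("count", "sum"),
        total_frequency=("frequency", "sum"),
    ).reset_index()
    out["cdr3_len"] = out["cdr3_set"].map(lambda s: len(s[0]))
    out["n_cdr3"] = out["cdr3_set"].map(len)
    return out


def brute_force_lineages(clonotypes: pd.DataFrame) -> pd.Series:
    """Independent all-pairs reference clustering (for small instances).

    Builds the explicit <=1-mismatch graph within every (animal, chain group,
    V, J, CDR3 length) stratum and extracts connected components with
    scipy.sparse.csgraph — a code path deliberately separate from the masked-bucket
    union-find used by :func:`cluster_lineages`.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    keys = clonotypes[LINEAGE_GROUP_KEY + ["cdr3_aa"]].drop_duplicates()
    keys["cdr3_len"] = keys["cdr3_aa"].str.len()
    lid = {}
    for group_vals, grp in keys.groupby(LINEAGE_GROUP_KEY + ["cdr3_len"], sort=True):
        cdr3s = sorted(grp["cdr3_aa"].tolist())
        arr = np.frombuffer("".join(cdr3s).encode(), dtype="S1").reshape(len(cdr3s), -1)
        dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        adj = csr_matrix(dist <= 1)
        _, labels = connected_components(adj, directed=False)
        context = "|".join(str(v) for v in group_vals[:-1])
        for comp in np.unique(labels):
            members = [cdr3s[i] for i in np.flatnonzero(labels == comp)]
            ref = lineage_id_for(members, context)
            for m in members:
                lid[group_vals[:-1] + (m,)] = ref
    idx = [tuple(r) for r in keys[LINEAGE_GROUP_KEY + ["cdr3_aa"]].to_numpy()]
    return pd.Series([lid[k] for k in idx], index=keys.index)
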