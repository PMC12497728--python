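"""Lineage phylogenies: fixed-length subsequences, p-distances, neighbor joining.

Because all member CDR3s of a lineage share one length, the concatenation of a
10-nt non-CDR3 V-region tail, the CDR3 nucleotide sequence, and the J-region
segment yields equal-length strings within a lineage, so trees can be built
from uncorrected pairwise distances without multiple sequence alignment.

The neighbor-joining implementation follows Saitou & Nei with the
Studier–Keppler Q-criterion; it is exact on additive distance matrices
(recovers the generating tree's topology and branch lengths).  Ties in the
Q-minimisation are broken by the lowest (row, column) index pair; negative
branch lengths are clamped to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LineageAlignment:
    """Equal-length subsequences of one lineage plus per-taxon annotations."""

    lineage_id: str
    taxa: list[str]
    sequences: list[str]
    annotations: pd.DataFrame

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class Tree:
    """Unrooted tree as a node list plus weighted edge list.

    ``labels[i]`` is the taxon name of node i, or None for internal nodes.
    """

    labels: list
    edges: list  # (node_a, node_b, branch_length)
    negative_branches_clamped: int = 0

    @property
    def n_leaves(self) -> int:
        return sum(1 for lab in self.labels if lab is not None)

    def _adjacency(self):
        adj = {i: [] for i in range(len(self.labels))}
        for a, b, w in self.edges:
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def newick(self, precision: int = 10) -> str:
        """Serialize as Newick, rooted for display at the last internal node
        (or at node 0 for a two-taxon tree)."""
        adj = self._adjacency()
        internals = [i for i, lab in enumerate(self.labels) if lab is None]
        root = internals[-1] if internals else 0

        def fmt(w):
            return f"{w:.{precision}g}"

        def walk(node, parent):
            children = [(nb, w) for nb, w in adj[node] if nb != parent]
            if not children:
                return self.labels[node]
            parts = [f"{walk(nb, node)}:{fmt(w)}" for nb, w in children]
            inner = f"({','.join(parts)})"
            return inner if self.labels[node] is None else f"{inner}{self.labels[node]}"

        return walk(root, None) + ";"

    def path_length_matrix(self) -> tuple[list, np.ndarray]:
        """Leaf labels and the matrix of summed branch lengths between leaves."""
        adj = self._adjacency()
        leaves = [i for i, lab in enumerate(self.labels) if lab is not None]
        n = len(self.labels)
        out = np.zeros((len(leaves), len(leaves)))
        for a, src in enumerate(leaves):
            dist = np.full(n, np.nan)
            dist[src] = 0.0
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if np.isnan(dist[v]):
                        dist[v] = dist[u] + w
                        stack.append(v)
            out[a] = dist[leaves]
        return [self.labels[i] for i in leaves], out


def extract_subsequence(record: pd.Series) -> str:
    """Concatenate v_tail_nt (10 nt) + cdr3 (nt) + j_region_nt for one record."""
    tail, cdr3, jreg = record["v_tail_nt"], record["cdr3"], record["j_region_nt"]
    if not tail or not cdr3 or not jreg or len(tail) != 10:
        raise ValueError(f"record {record.get('sequence_id')}: missing or malformed segments")
    return tail + cdr3 + jreg


def build_alignment(lineage_records: pd.DataFrame, lineage_id: str) -> LineageAlignment:
    """Collapse a lineage's records into unique subsequences with annotations.

    Duplicate subsequences are merged into one taxon whose multiplicity,
    pooled mutation rate, majority isotype, and sample list are recorded.
    NJ degenerates on zero-distance pairs, and displaying unique sequences
    matches how lineage trees are read.
    """
    df = lineage_records.copy()
    df["subsequence"] = [extract_subsequence(row) for _, row in df.iterrows()]
    lengths = df["subsequence"].str.len().unique()
    if len(lengths) > 1:
        raise ValueError(f"lineage {lineage_id}: unequal subsequence lengths {lengths}")

    taxa, seqs, rows = [], [], []
    df["sample"] = df["animal_id"].astype(str) + "_" + df["timepoint_hr"].astype(str) + "hr"
    for i, (seq, grp) in enumerate(sorted(df.groupby("subsequence"), key=lambda kv: kv[0])):
        label = f"seq{i + 1}"
        num = (grp["v_mismatches"] + grp["j_mismatches"]) * grp["duplicate_count"]
        den = (grp["v_aligned_len"] + grp["j_aligned_len"]) * grp["duplicate_count"]
        iso = grp.groupby("isotype")["duplicate_count"].sum().idxmax()
        taxa.append(label)
        seqs.append(seq)
        rows.append(
            {
                "taxon": label,
                "multiplicity": int(grp["duplicate_count"].sum()),
                "mutation_rate": 100.0 * num.sum() / den.sum(),
                "isotype": iso,
                "samples": ";".join(sorted(grp["sample"].unique())),
            }
        )
    if len(taxa) < 2:
        raise ValueError(f"lineage {lineage_id}: need >= 2 distinct subsequences for a tree")
    return LineageAlignment(lineage_id, taxa, seqs, pd.DataFrame(rows))


def distance_matrix(aln: LineageAlignment, model: str = "p") -> np.ndarray:
    """Pairwise distances between subsequences.

    ``model='p'`` (default): uncorrected mismatch fraction.  ``model='jc'``:
    Jukes–Cantor correction −(3/4)·ln(1 − 4p/3).
    """
    arr = np.frombuffer("".join(aln.sequences).encode(), dtype="S1").reshape(
        len(aln.sequences), -1
    )
    p = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    if model == "p":
        return p
    if model == "jc":
        if (p >= 0.75).any():
            raise ValueError("Jukes–Cantor undefined for p-distance >= 0.75")
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown distance model {model!r}")


def neighbor_joining(d, labels) -> Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimising Q(i,j) = (n−2)·d(i,j) − r_i − r_j,
    assigns branch lengths from the net divergences, and reduces the matrix.
    Returns an unrooted :class:`Tree`; exact on additive matrices.
    """
    d = np.asarray(d, dtype=float).copy()
    labels = list(labels)
    n = d.shape[0]
    if d.shape != (n, n) or n < 2 or len(labels) != n:
        raise ValueError("need a square matrix with one label per row")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    tree_labels: list = list(labels)
    edges: list = []
    clamped = 0
    active = list(range(n))  # active tree-node ids
    # d is indexed by position within `active`

    def _clamp(w):
        nonlocal clamped
        if w < 0:
            clamped += 1
            return 0.0
        return float(w)

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum in row-major order:
        i, j = divmod(flat, m)    # lowest (row, column) tie-break
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new_id = len(tree_labels)
        tree_labels.append(None)
        edges.append((active[i], new_id, _clamp(li)))
        edges.append((active[j], new_id, _clamp(lj)))
        d_new = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], d_new[keep]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new_id]

    if len(active) == 3:
        a, b, c = 0, 1, 2
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        center = len(tree_labels)
        tree_labels.append(None)
        for node, length in zip(active, (la, lb, lc)):
            edges.append((node, center, _clamp(length)))
    elif len(active) == 2:
        edges.append((active[0], active[1], _clamp(d[0, 1])))

    return Tree(tree_labels, edges, negative_branches_clamped=clamped)


def write_newick(
    tree: Tree, path: str | Path, annotations: pd.DataFrame | None = None
) -> Path:
    """Write a Newick file; annotations go to a sidecar TSV keyed by taxon."""
    path = Path(path)
    path.write_text(tree.newick() + "\n")
    if annotations is not None:
        annotations.to_csv(path.with_suffix(path.suffix + ".annotations.tsv"),
                           sep="\t", index=False)
    return path
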