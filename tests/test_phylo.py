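import dendropy
import numpy as np
import pandas as pd
import pytest

from bcrdyn import phylo
from conftest import make_records


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with positive branch lengths.

    Returns (labels, path-length matrix, newick string).  Built by random
    sequential joining, independent of the neighbor-joining code under test.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = list(range(n_taxa))
    tree_labels = list(labels)
    edges = []
    active = list(nodes)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        new = len(tree_labels)
        tree_labels.append(None)
        edges.append((active[i], new, float(rng.uniform(0.05, 1.0))))
        edges.append((active[j], new, float(rng.uniform(0.05, 1.0))))
        active = [a for k, a in enumerate(active) if k not in (i, j)] + [new]
    edges.append((active[0], active[1], float(rng.uniform(0.05, 1.0))))
    ref = phylo.Tree(tree_labels, edges)
    leaf_labels, dist = ref.path_length_matrix()
    order = [leaf_labels.index(lab) for lab in labels]
    return labels, dist[np.ix_(order, order)], ref.newick()


def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestExtractSubsequence:
    def test_concatenation_length(self):
        rec = make_records([{"cdr3_aa": "A" * 12, "j_region_nt": "ACGT" * 5}]).iloc[0]
        assert len(phylo.extract_subsequence(rec)) == 10 + 36 + 20

    def test_missing_segment_rejected(self):
        rec = make_records([{"v_tail_nt": ""}]).iloc[0]
        with pytest.raises(ValueError):
            phylo.extract_subsequence(rec)


class TestDistanceMatrix:
    def _aln(self, seqs):
        return phylo.LineageAlignment(
            "L", [f"s{i}" for i in range(len(seqs))], seqs, pd.DataFrame())

    def test_identical_pair_is_zero(self):
        d = phylo.distance_matrix(self._aln(["ACGT" * 19, "ACGT" * 19]))
        assert d[0, 1] == 0.0

    def test_two_mismatches_over_76(self):
        a = "A" * 76
        b = "C" + "A" * 74 + "C"
        assert phylo.distance_matrix(self._aln([a, b]))[0, 1] == pytest.approx(
            2 / 76, abs=1e-9)

    def test_symmetric_zero_diagonal(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(10)]
        d = phylo.distance_matrix(self._aln(seqs))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_jukes_cantor_exceeds_p_distance(self):
        a, b = "A" * 100, "C" * 20 + "A" * 80
        aln = self._aln([a, b])
        p = phylo.distance_matrix(aln, model="p")[0, 1]
        jc = phylo.distance_matrix(aln, model="jc")[0, 1]
        assert jc > p


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = phylo.neighbor_joining([[0, 0.42], [0.42, 0]], ["A", "B"])
        assert tree.n_leaves == 2
        assert tree.edges[0][2] == pytest.approx(0.42)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3),(C:4,D:5)) with internal edge 1
        d = np.array(
            [[0, 5, 7, 8],
             [5, 0, 8, 9],
             [7, 8, 0, 9],
             [8, 9, 9, 0]], dtype=float)
        tree = phylo.neighbor_joining(d, ["A", "B", "C", "D"])
        labels, pl = tree.path_length_matrix()
        order = [labels.index(x) for x in "ABCD"]
        assert np.allclose(pl[np.ix_(order, order)], d, atol=1e-9)
        assert rf_distance(tree.newick(), "((A:2,B:3):1,(C:4,D:5));") == 0

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_additive_matrices_reproduce_generating_tree(self, rng, n_taxa):
        labels, d, ref_newick = random_additive_tree(rng, n_taxa)
        tree = phylo.neighbor_joining(d, labels)
        out_labels, pl = tree.path_length_matrix()
        order = [out_labels.index(x) for x in labels]
        assert np.allclose(pl[np.ix_(order, order)], d, atol=1e-9)
        assert rf_distance(tree.newick(), ref_newick) == 0

    def test_unrooted_internal_node_count(self, rng):
        labels, d, _ = random_additive_tree(rng, 7)
        tree = phylo.neighbor_joining(d, labels)
        assert sum(1 for lab in tree.labels if lab is None) == 7 - 2

    def test_taxon_permutation_invariance(self, rng):
        labels, d, _ = random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        t1 = phylo.neighbor_joining(d, labels)
        t2 = phylo.neighbor_joining(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert rf_distance(t1.newick(), t2.newick()) == 0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining([[0, 1], [2, 0]], ["A", "B"])

    def test_negative_branches_clamped_and_flagged(self):
        # strongly non-additive matrix forces a negative internal estimate
        d = np.array(
            [[0, 1.0, 1.0, 10.0],
             [1.0, 0, 10.0, 1.0],
             [1.0, 10.0, 0, 1.0],
             [10.0, 1.0, 1.0, 0]])
        tree = phylo.neighbor_joining(d, list("ABCD"))
        assert all(w >= 0 for _, _, w in tree.edges)


class TestAlignmentAndNewick:
    def _lineage_records(self):
        return make_records(
            [
                {"cdr3_aa": "CAAAAAAAF", "duplicate_count": 4, "timepoint_hr": 0},
                {"cdr3_aa": "CAAAAAAAF", "duplicate_count": 2, "timepoint_hr": 48},
                {"cdr3_aa": "CAAAAAAWF", "duplicate_count": 1, "timepoint_hr": 48,
                 "v_mismatches": 5},
                {"cdr3_aa": "CAAAAAAYF", "duplicate_count": 1, "timepoint_hr": 72},
            ]
        )

    def test_duplicate_subsequences_collapse_with_multiplicity(self):
        aln = phylo.build_alignment(self._lineage_records(), "L1")
        assert len(aln.taxa) == 3
        assert sorted(aln.annotations["multiplicity"]) == [1, 1, 6]
        assert aln.annotations["samples"].str.contains("M1_0hr").any()

    def test_equal_subsequence_lengths_within_lineage(self):
        aln = phylo.build_alignment(self._lineage_records(), "L1")
        assert len({len(s) for s in aln.sequences}) == 1

    def test_newick_round_trip_and_sidecar(self, tmp_path):
        aln = phylo.build_alignment(self._lineage_records(), "L1")
        tree = phylo.neighbor_joining(phylo.distance_matrix(aln), aln.taxa)
        path = phylo.write_newick(tree, tmp_path / "lin.nwk", aln.annotations)
        reparsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {t.label for t in reparsed.taxon_namespace} == set(aln.taxa)
        assert rf_distance(path.read_text(), tree.newick()) == 0
        sidecar = pd.read_csv(
            tmp_path / "lin.nwk.annotations.tsv", sep="\t")
        assert len(sidecar) == len(aln.taxa)
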