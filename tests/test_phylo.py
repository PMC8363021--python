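"""Anchor alignment, p-distances, neighbor joining, monophyly."""

import numpy as np
import pytest

from _oracles import oracle_monophyly, oracle_nj, tree_edges
from nrminer.config import RunConfig
from nrminer.phylo import (
    AnchoredDBD,
    DistanceMatrix,
    anchor_align,
    check_monophyly,
    nj_tree,
    pairwise_p_distance,
)
from nrminer.simulate import SAFE_ALPHABET, build_dbd

ANCHORS = (0, 3, 17, 20, 30, 36, 46, 49)


def random_dbd(rng, rid):
    dbox = "".join(rng.choice(list(SAFE_ALPHABET), size=5))
    return AnchoredDBD(
        id=rid, sequence=build_dbd("CEGCKGFFRR", dbox, False, rng), anchors=ANCHORS
    )


class TestAnchorAlignment:
    def test_identical_rows_have_no_gaps(self, rng):
        d = random_dbd(rng, "a")
        aln = anchor_align([d, AnchoredDBD("b", d.sequence, d.anchors)])
        assert "-" not in aln.rows[0] + aln.rows[1]
        assert aln.rows[0] == aln.rows[1]

    def test_two_extra_linker_residues_give_two_gap_columns(self, rng):
        d = random_dbd(rng, "short")
        longer = d.sequence[:28] + "AA" + d.sequence[28:]
        anchors_long = tuple(a if a < 28 else a + 2 for a in ANCHORS)
        aln = anchor_align(
            [d, AnchoredDBD("long", longer, anchors_long)]
        )
        assert aln.rows[0].count("-") == 2
        assert aln.rows[1].count("-") == 0

    def test_anchor_columns_gap_free_and_rows_degap_to_source(self, rng):
        dbds = [random_dbd(rng, f"d{i}") for i in range(6)]
        # vary linker lengths
        extended = []
        for i, d in enumerate(dbds):
            ins = "A" * (i % 3)
            seq = d.sequence[:28] + ins + d.sequence[28:]
            anchors = tuple(a if a < 28 else a + len(ins) for a in ANCHORS)
            extended.append(AnchoredDBD(d.id, seq, anchors))
        aln = anchor_align(extended)
        for col in aln.anchor_columns:
            assert all(row[col] != "-" for row in aln.rows)
        for i, d in enumerate(extended):
            assert aln.degap(i) == d.sequence

    def test_p_distance_matches_column_recount(self, rng):
        dbds = [random_dbd(rng, f"d{i}") for i in range(4)]
        aln = anchor_align(dbds)
        mat = pairwise_p_distance(aln)
        for i in range(4):
            for j in range(4):
                a, b = aln.rows[i], aln.rows[j]
                cols = [
                    (x, y) for x, y in zip(a, b) if x != "-" and y != "-"
                ]
                expect = (
                    sum(x != y for x, y in cols) / len(cols) if i != j else 0.0
                )
                assert mat.values[i, j] == pytest.approx(expect)

    def test_alignment_exports_round_trip(self, rng, tmp_path):
        from nrminer.io import read_fasta
        from nrminer.phylo import write_alignment_fasta, write_alignment_phylip

        dbds = [random_dbd(rng, f"d{i}") for i in range(3)]
        aln = anchor_align(dbds)
        fasta = tmp_path / "aln.fasta"
        write_alignment_fasta(aln, fasta)
        lines = fasta.read_text().splitlines()
        assert lines[0] == ">d0" and lines[1] == aln.rows[0]
        phylip = tmp_path / "aln.phy"
        write_alignment_phylip(aln, phylip)
        header = phylip.read_text().splitlines()[0].split()
        assert header == [str(len(aln)), str(aln.n_columns)]

    def test_sparse_overlap_forced_to_one(self):
        cfg = RunConfig(min_comparable_columns=60)
        a = AnchoredDBD("a", "C" * 50, ANCHORS)
        b = AnchoredDBD("b", "C" * 50, ANCHORS)
        with pytest.warns(UserWarning, match="comparable"):
            mat = pairwise_p_distance(anchor_align([a, b]), cfg)
        assert mat.values[0, 1] == 1.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ("A", "B", "C")
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(ids, d))
        edges = tree_edges(tree)
        assert edges[frozenset({"A"})] == pytest.approx((5 + 9 - 8) / 2)
        assert edges[frozenset({"B"})] == pytest.approx((5 + 8 - 9) / 2)
        assert edges[frozenset({"C"})] == pytest.approx((9 + 8 - 5) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):5,C:3,D:4) -> additive distances
        ids = ("A", "B", "C", "D")
        d = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(ids, d))
        edges = tree_edges(tree)
        assert edges[frozenset({"A"})] == pytest.approx(1)
        assert edges[frozenset({"B"})] == pytest.approx(2)
        assert edges[frozenset({"C"})] == pytest.approx(3)
        assert edges[frozenset({"D"})] == pytest.approx(4)
        assert edges[frozenset({"A", "B"})] == pytest.approx(5)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_naive_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        ids = tuple("ABCDEF")
        m = rng.uniform(0.05, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ours = tree_edges(nj_tree(DistanceMatrix(ids, m)))
        full = frozenset(ids)

        def canon(s):
            return min(s, full - s, key=lambda x: (len(x), sorted(x)))

        oracle = {canon(k): v for k, v in oracle_nj(ids, m).items()}
        assert set(ours) == set(oracle)
        for split in ours:
            assert ours[split] == pytest.approx(oracle[split], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recover_generating_topology(self, seed):
        import dendropy

        rng = np.random.default_rng(100 + seed)
        taxa = [f"T{i}" for i in range(7)]
        true_tree, dist = _random_additive(taxa, rng)
        ours = nj_tree(DistanceMatrix(tuple(taxa), dist))
        true_splits = {
            s for s in tree_edges(true_tree) if 1 < len(s) < len(taxa) - 1
        }
        our_splits = {
            s for s in tree_edges(ours) if 1 < len(s) < len(taxa) - 1
        }
        assert true_splits == our_splits

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(0)
        taxa = [f"T{i}" for i in range(6)]
        _, dist = _random_additive(taxa, rng)
        ours = tree_edges(nj_tree(DistanceMatrix(tuple(taxa), dist)))
        sk_tree = sk_nj(SkDM(dist, ids=taxa))
        sk_splits = set()
        for node in sk_tree.traverse(include_self=False):
            tips = frozenset(t.name for t in node.tips()) or frozenset({node.name})
            full = frozenset(taxa)
            sk_splits.add(min(tips, full - tips, key=lambda s: (len(s), sorted(s))))
        our_splits = {s for s in ours if 1 < len(s) < len(taxa) - 1}
        sk_internal = {s for s in sk_splits if 1 < len(s) < len(taxa) - 1}
        assert our_splits == sk_internal


def _random_additive(taxa, rng):
    """Random binary tree with positive branch lengths + its distance matrix."""
    import dendropy

    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1, rng=_PyRng(rng)
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.5, 3.0))
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    dist = np.zeros((n, n))
    for i, t1 in enumerate(tns):
        for j, t2 in enumerate(tns):
            if i != j:
                dist[i, j] = pdm.distance(t1, t2)
    return tree, dist


class _PyRng:
    """Adapter: numpy Generator -> the random.Random calls dendropy makes."""

    def __init__(self, rng):
        self._rng = rng

    def sample(self, population, k):
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[int(i)] for i in idx]

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def expovariate(self, lam):
        return float(self._rng.exponential(1.0 / lam))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def random(self):
        return float(self._rng.random())

    def shuffle(self, x):
        self._rng.shuffle(x)

    def choice(self, seq):
        return seq[int(self._rng.integers(len(seq)))]


class TestMonophyly:
    def _tree(self, newick):
        import dendropy

        return dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)

    def test_clean_cherry_is_monophyletic(self):
        tree = self._tree("((A1,A2),(B1,B2));")
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        ok, edge = check_monophyly(tree, labels, "A")
        assert ok and edge is not None

    def test_interleaved_labels_are_not(self):
        tree = self._tree("((A1,B1),(A2,B2));")
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        ok, edge = check_monophyly(tree, labels, "A")
        assert not ok and edge is None

    def test_absent_label_rejected(self):
        tree = self._tree("((A1,A2),(B1,B2));")
        with pytest.raises(ValueError, match="absent"):
            check_monophyly(tree, {"A1": "A"}, "Z")

    def test_symmetric_under_relabeling(self):
        tree = self._tree("((A1,A2),(B1,B2));")
        labels = {"A1": "x", "A2": "x", "B1": "y", "B2": "y"}
        ok_x, _ = check_monophyly(tree, labels, "x")
        swapped = {k: ("y" if v == "x" else "x") for k, v in labels.items()}
        ok_y, _ = check_monophyly(tree, swapped, "y")
        assert ok_x == ok_y

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_edge_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"L{i}" for i in range(8)]
        tree, _ = _random_additive(taxa, rng)
        k = int(rng.integers(1, 8))
        target = set(str(t) for t in rng.choice(taxa, size=k, replace=False))
        labels = {t: ("in" if t in target else "out") for t in taxa}
        ours, _ = check_monophyly(tree, labels, "in")
        assert ours == oracle_monophyly(tree, target)
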