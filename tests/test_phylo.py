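"""NJ construction, bootstrap, concatenation, monophyly, Newick I/O."""

import itertools
import random

import numpy as np
import pytest

from grassbarcode import (
    AlignedBlock,
    ComputationError,
    DataValidationError,
    DistanceModel,
    bootstrap_support,
    concatenate,
    distance_matrix,
    is_monophyletic,
    nj_tree,
    read_newick,
    write_newick,
)
from grassbarcode.distances import DistanceMatrix
from grassbarcode.phylo import _splits


def matrix_from_array(ids, values) -> DistanceMatrix:
    arr = np.asarray(values, dtype=float)
    return DistanceMatrix(
        accession_ids=tuple(ids),
        values=arr,
        model=DistanceModel.P_DISTANCE,
        gamma_shape=None,
        site_counts=np.full(arr.shape, 100, dtype=int),
    )


# ---------------------------------------------------------------------------
# independent oracle: random additive trees via a plain edge-list graph
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, rnd: random.Random):
    """Random unrooted binary tree; returns (edges, leaf names).

    edges: dict[(u, v)] -> length with u < v, nodes as ints; leaves are 0..n-1.
    """
    next_node = n_leaves
    center = next_node
    next_node += 1
    edges = {}
    for leaf in range(3):
        edges[(leaf, center)] = rnd.uniform(0.1, 1.0)
    for leaf in range(3, n_leaves):
        u, v = rnd.choice(list(edges))
        length = edges.pop((u, v))
        mid = next_node
        next_node += 1
        edges[tuple(sorted((u, mid)))] = length / 2
        edges[tuple(sorted((v, mid)))] = length / 2
        edges[tuple(sorted((leaf, mid)))] = rnd.uniform(0.1, 1.0)
    return edges


def path_length_matrix(edges, n_leaves):
    """All-pairs leaf distances by breadth-first traversal of the edge list."""
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    return D


def true_splits(edges, n_leaves):
    """Non-trivial leaf bipartitions of the edge-list tree (anchor-free side)."""
    leaves = [f"L{i}" for i in range(n_leaves)]
    out = set()
    for cut in edges:
        adj = {}
        for (u, v), _ in edges.items():
            if (u, v) == cut:
                continue
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        seen = {cut[0]}
        stack = [cut[0]]
        while stack:
            node = stack.pop()
            for nbr in adj.get(node, []):
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        side = frozenset(f"L{i}" for i in range(n_leaves) if i in seen)
        if 1 < len(side) < n_leaves - 1:
            if "L0" in side:
                side = frozenset(leaves) - side
            out.add(side)
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = [[0, 5, 9], [5, 0, 10], [9, 10, 0]]
        tree = nj_tree(matrix_from_array(["A", "B", "C"], D))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        D = [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]]
        tree = nj_tree(matrix_from_array("ABCD", D))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert tree.total_branch_length == pytest.approx(15.0)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_leaves):
        """NJ is consistent: exact recovery of topology and branch lengths."""
        rnd = random.Random(n_leaves * 101)
        for _ in range(10):
            edges = random_additive_tree(n_leaves, rnd)
            D = path_length_matrix(edges, n_leaves)
            ids = [f"L{i}" for i in range(n_leaves)]
            tree = nj_tree(matrix_from_array(ids, D))
            assert tree.bipartitions() == true_splits(edges, n_leaves)
            pdm = tree.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.tree.taxon_namespace}
            for i, j in itertools.combinations(range(n_leaves), 2):
                got = pdm.distance(taxa[f"L{i}"], taxa[f"L{j}"])
                assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        """Independent implementation cross-check on a perturbed additive matrix."""
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rnd = random.Random(7)
        edges = random_additive_tree(6, rnd)
        D = path_length_matrix(edges, 6)
        noise = np.array(
            [[rnd.uniform(0, 0.01) for _ in range(6)] for _ in range(6)]
        )
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        D = D + noise
        D = (D + D.T) / 2  # exact symmetry for skbio's strict validator
        ids = [f"L{i}" for i in range(6)]
        mine = nj_tree(matrix_from_array(ids, D))
        theirs = skbio_tree.nj(SkbioDM(D, ids))
        import dendropy

        dtree = dendropy.Tree.get(
            data=str(theirs).replace("root", ""), schema="newick"
        )
        dtree.is_rooted = False
        assert mine.bipartitions() == frozenset(_splits(dtree))

    def test_all_equal_distances_tie_breaks_to_lowest_pair(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(matrix_from_array("ABCD", D))
        # lowest-index pair (A, B) joined first => split AB|CD
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_leaf_permutation_gives_isomorphic_tree(self):
        rnd = random.Random(3)
        edges = random_additive_tree(6, rnd)
        D = path_length_matrix(edges, 6)
        ids = [f"L{i}" for i in range(6)]
        base = nj_tree(matrix_from_array(ids, D)).bipartitions()
        perm = [3, 1, 5, 0, 4, 2]
        D2 = D[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        assert nj_tree(matrix_from_array(ids2, D2)).bipartitions() == base

    def test_negative_branches_clamped_and_logged(self):
        # violating the triangle inequality forces a negative estimate
        D = [[0, 10, 1, 1], [10, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]]
        tree = nj_tree(matrix_from_array("ABCD", D))
        assert tree.n_clamped >= 1
        assert tree.clamped_total > 0
        assert all(
            (e.length or 0) >= 0
            for e in tree.tree.edges()
            if e.tail_node is not None
        )

    def test_two_taxa_degenerate(self):
        tree = nj_tree(matrix_from_array("AB", [[0, 4], [4, 0]]))
        assert tree.total_branch_length == pytest.approx(4.0)
        assert tree.leaf_labels == frozenset("AB")

    def test_undefined_entries_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ComputationError, match="undefined pair"):
            nj_tree(matrix_from_array("ABC", D))


class TestConcatenate:
    def test_offsets_recorded(self):
        ids = ("x", "y")
        blocks = {
            "m1": AlignedBlock(ids, ("A" * 400, "C" * 400)),
            "m2": AlignedBlock(ids, ("G" * 572, "T" * 572)),
            "m3": AlignedBlock(ids, ("A" * 470, "G" * 470)),
        }
        concat = concatenate(blocks, ["m1", "m2", "m3"])
        assert concat.length == 1442
        assert concat.offsets == {
            "m1": (0, 400),
            "m2": (400, 972),
            "m3": (972, 1442),
        }

    def test_single_block_identity(self):
        block = AlignedBlock(("x", "y"), ("ACGT", "ACGA"))
        concat = concatenate({"m": block}, ["m"])
        assert concat.block.sequences == block.sequences

    def test_accession_mismatch_names_difference(self):
        blocks = {
            "m1": AlignedBlock(("x", "y"), ("AC", "GT")),
            "m2": AlignedBlock(("x", "z"), ("AC", "GT")),
        }
        with pytest.raises(DataValidationError, match="differ"):
            concatenate(blocks, ["m1", "m2"])

    def test_fixture_four_marker_total_length(self, panel, blocks):
        """A. cristatum's concatenated ungapped length is 697+395+572+463."""
        concat = concatenate(blocks, panel.marker_ids)
        seq = concat.block.sequence("Agr_cris_cristatum")
        assert len(seq.replace("-", "")) == 2127


class TestBootstrap:
    # 2-column alignment: col 1 supports AB|CD, col 2 supports AC|BD
    TAXA = ("A", "B", "C", "D")
    SEQS = ("AA", "AG", "CA", "CG")

    def exhaustive_expectation(self):
        """Oracle: enumerate all 4 ordered column resamples exactly."""
        cols = [tuple(s[i] for s in self.SEQS) for i in range(2)]
        base = nj_tree(distance_matrix(AlignedBlock(self.TAXA, self.SEQS), "num_diff"))
        targets = base.bipartitions()
        hits = {t: 0 for t in targets}
        outcomes = list(itertools.product(range(2), repeat=2))
        for pick in outcomes:
            seqs = tuple(
                "".join(cols[c][row] for c in pick) for row in range(4)
            )
            rep = nj_tree(distance_matrix(AlignedBlock(self.TAXA, seqs), "num_diff"))
            reps = rep.bipartitions()
            for t in targets:
                if t in reps:
                    hits[t] += 1
        return {t: 100.0 * h / len(outcomes) for t, h in hits.items()}

    def test_monte_carlo_converges_to_enumeration(self):
        expected = self.exhaustive_expectation()
        tree = bootstrap_support(
            AlignedBlock(self.TAXA, self.SEQS),
            model="num_diff",
            replicates=4000,
            seed=9,
        )
        for split, exp in expected.items():
            assert tree.support[split] == pytest.approx(exp, abs=3.0)

    def test_conflict_free_columns_give_full_support(self):
        # every column supports AB|CD: support must be exactly 100
        block = AlignedBlock(self.TAXA, ("A" * 20, "A" * 20, "G" * 20, "G" * 20))
        tree = bootstrap_support(block, model="num_diff", replicates=200, seed=1)
        assert tree.support[frozenset({"C", "D"})] == 100.0

    def test_same_seed_reproduces_supports(self, blocks, panel):
        concat = concatenate(blocks, panel.marker_ids)
        a = bootstrap_support(concat, replicates=30, seed=5)
        b = bootstrap_support(concat, replicates=30, seed=5)
        assert a.support == b.support
        assert a.newick() == b.newick()

    def test_replicates_must_be_positive(self, blocks):
        with pytest.raises(DataValidationError, match="replicates"):
            bootstrap_support(blocks["rbcL"], replicates=0)

    def test_supports_within_bounds(self, blocks, panel):
        concat = concatenate(blocks, panel.marker_ids)
        tree = bootstrap_support(concat, replicates=25, seed=2)
        assert all(0.0 <= v <= 100.0 for v in tree.support.values())


class TestMonophyly:
    @pytest.fixture()
    def four_taxon_tree(self):
        D = [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]]
        return nj_tree(matrix_from_array("ABCD", D))

    def test_brute_force_over_all_subsets(self, four_taxon_tree):
        """((A,B),(C,D)): check every leaf subset against the 5-edge truth."""
        expected_true = [
            {"A"}, {"B"}, {"C"}, {"D"},
            {"A", "B"}, {"C", "D"},
            # complements of the above, and the full / (n-1) sets
            {"A", "B", "C"}, {"A", "B", "D"}, {"A", "C", "D"}, {"B", "C", "D"},
            {"A", "B", "C", "D"},
        ]
        for r in range(1, 5):
            for combo in itertools.combinations("ABCD", r):
                subset = set(combo)
                assert is_monophyletic(four_taxon_tree, subset) == (
                    subset in expected_true
                )

    def test_unknown_leaf_rejected(self, four_taxon_tree):
        with pytest.raises(DataValidationError, match="unknown leaf"):
            is_monophyletic(four_taxon_tree, {"Z"})
        with pytest.raises(DataValidationError, match="empty"):
            is_monophyletic(four_taxon_tree, set())


class TestNewickIO:
    def test_round_trip_identical_string(self, tmp_path, blocks, panel):
        concat = concatenate(blocks, panel.marker_ids)
        tree = bootstrap_support(concat, replicates=20, seed=4)
        p1 = tmp_path / "a.nwk"
        write_newick(tree, p1)
        reread = read_newick(p1)
        p2 = tmp_path / "b.nwk"
        write_newick(reread, p2)
        assert p1.read_text() == p2.read_text()
        assert reread.leaf_labels == tree.leaf_labels

    def test_three_taxon_shape(self, tmp_path):
        tree = nj_tree(matrix_from_array("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text.startswith("(") and text.endswith(";")
        assert text.count(",") == 2  # (A:x,B:y,C:z);

    def test_support_labels_after_closing_parens(self, tmp_path):
        block = AlignedBlock(("A", "B", "C", "D"), ("A" * 9, "A" * 9, "G" * 9, "G" * 9))
        tree = bootstrap_support(block, model="num_diff", replicates=50, seed=0)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert ")100:" in path.read_text()

    def test_malformed_newick_raises(self, tmp_path):
        bad = tmp_path / "bad.nwk"
        bad.write_text("((A:1,B:2;")
        with pytest.raises(DataValidationError, match="malformed Newick"):
            read_newick(bad)
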