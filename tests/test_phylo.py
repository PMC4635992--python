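import itertools

import numpy as np
import pytest

from arffam.io import SequenceRecord
from arffam.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    assign_groups,
    bootstrap_support,
    find_sister_pairs,
    neighbor_joining,
    pairwise_distance,
)


def aln(seqs: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v, "protein") for k, v in seqs.items()])


# ---------------------------------------------------------------------------
# oracles


def random_additive(n_leaves: int, rng: np.random.Generator):
    """Random binary tree topology + branch lengths; returns (tree, matrix)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode(children=[a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 1.0))
    tree = PhyloTree(TreeNode(children=nodes))
    return tree, tree.leaf_distances()


def enumerate_topologies(labels):
    """All unrooted binary topologies, as frozensets of bipartitions.

    Built by inserting leaves one at a time into every edge; each topology is
    returned as (edges, n_nodes) where edges are (u, v) over integer node ids
    and leaf i is node i.
    """
    n = len(labels)
    base = [[(0, n), (1, n), (2, n)]]  # star on the first 3 leaves
    trees = [(base[0], n + 1)]
    for leaf in range(3, n):
        grown = []
        for edges, n_nodes in trees:
            for k, (u, v) in enumerate(edges):
                new_inner = n_nodes
                new_edges = edges[:k] + edges[k + 1:] + [
                    (u, new_inner), (v, new_inner), (leaf, new_inner)
                ]
                grown.append((new_edges, n_nodes + 1))
        trees = grown
    return trees


def topology_bipartitions(edges, n_leaves):
    """Bipartitions (as canonical frozensets of leaf ids) of an edge list."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side(u, v):
        seen = {v, u}
        stack = [u]
        leaves = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                leaves.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return leaves

    out = set()
    for u, v in edges:
        s = frozenset(side(u, v))
        if 2 <= len(s) <= n_leaves - 2:
            out.add(s if 0 not in s else frozenset(range(n_leaves)) - s)
    return frozenset(out)


def ls_residual(edges, n_leaves, dm: np.ndarray) -> float:
    """Least-squares branch-length fit residual for a topology."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))

    def path(a, b):
        stack = [(a, [])]
        seen = {a}
        while stack:
            x, used = stack.pop()
            if x == b:
                return used
            for nxt, eidx in adj[x]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, used + [eidx]))
        raise AssertionError("disconnected topology")

    for r, (a, b) in enumerate(pairs):
        for eidx in path(a, b):
            A[r, eidx] = 1.0
        y[r] = dm[a, b]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


# ---------------------------------------------------------------------------


class TestPairwiseDistance:
    def test_identical_zero(self):
        d = pairwise_distance(aln({"a": "MKLV", "b": "MKLV", "c": "MKLV"}), "p_distance")
        assert np.all(d.d == 0)

    def test_one_mismatch_in_ten(self):
        s = "AAAAAAAAAA"
        d = pairwise_distance(aln({"a": s, "b": "C" + s[1:], "c": s}), "p_distance")
        assert d.d[0, 1] == pytest.approx(0.1)

    def test_poisson_correction_value(self):
        s = "AAAAAAAAAA"
        d = pairwise_distance(aln({"a": s, "b": "C" + s[1:], "c": s}), "poisson")
        assert d.d[0, 1] == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_gaps_use_pairwise_deletion(self):
        d = pairwise_distance(
            aln({"a": "MK-VA", "b": "MKLVC", "c": "MKLVA"}), "p_distance"
        )
        # a vs b: 4 shared columns, 1 mismatch
        assert d.d[0, 1] == pytest.approx(0.25)

    def test_poisson_dominates_p_distance(self):
        rng = np.random.default_rng(0)
        alpha = "ACDEFGHIKL"
        seqs = {
            f"s{i}": "".join(rng.choice(list(alpha), 50)) for i in range(5)
        }
        p = pairwise_distance(aln(seqs), "p_distance").d
        q = pairwise_distance(aln(seqs), "poisson").d
        assert np.all(q >= p - 1e-12)

    def test_saturated_poisson_raises(self):
        with pytest.raises(ValueError, match="p_distance"):
            pairwise_distance(aln({"a": "AAAA", "b": "CCCC", "c": "AAAA"}), "poisson")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_recovers_known_additive_tree(self):
        # ((A:1,B:2):1,C:3,D:4): path-sum distance matrix
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            float,
        )
        d[3, 2] = d[2, 3] = 7
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert frozenset(["A", "B"]) in tree.bipartitions() or frozenset(["C", "D"]) in tree.bipartitions()
        induced = tree.leaf_distances()
        order = [induced.labels.index(l) for l in labels]
        assert np.allclose(induced.d[np.ix_(order, order)], d, atol=1e-9)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_additive_matrices_reinduced_exactly(self, n_leaves):
        rng = np.random.default_rng(42)
        for _ in range(10):
            true_tree, dm = random_additive(n_leaves, rng)
            nj = neighbor_joining(dm)
            induced = nj.leaf_distances()
            order = [induced.labels.index(l) for l in dm.labels]
            assert np.allclose(induced.d[np.ix_(order, order)], dm.d, atol=1e-8)

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_topology_matches_exhaustive_least_squares_oracle(self, n_leaves):
        """On additive matrices the NJ topology is the unique topology whose
        least-squares branch fit has zero residual, over all unrooted
        topologies."""
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(n_leaves)]
        for _ in range(3):
            _, dm = random_additive(n_leaves, rng)
            order = [dm.labels.index(l) for l in labels]
            D = dm.d[np.ix_(order, order)]
            zero_res = [
                topology_bipartitions(edges, n_leaves)
                for edges, _ in enumerate_topologies(labels)
                if ls_residual(edges, n_leaves, D) < 1e-16
            ]
            assert len(zero_res) == 1
            nj = neighbor_joining(DistanceMatrix(labels, D))
            # canonicalize NJ bipartitions to leaf-id sets anchored at leaf 0
            full = frozenset(range(n_leaves))
            canon = set()
            for side in nj.bipartitions():
                ids = frozenset(labels.index(x) for x in side)
                canon.add(ids if 0 not in ids else full - ids)
            assert frozenset(canon) == zero_res[0]

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_deterministic_under_ties(self):
        # fully tied matrix: joins must follow lexicographic label order
        labels = ["d", "b", "a", "c"]
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(DistanceMatrix(labels, d.copy()))
        t2 = neighbor_joining(DistanceMatrix(labels, d.copy()))
        assert t1.to_newick() == t2.to_newick()
        # the first join is the lexicographically smallest pair (a, b);
        # the split is stored canonically as the side without the anchor leaf
        assert frozenset(["c", "d"]) in t1.bipartitions()


class TestNewickInterop:
    def test_dendropy_roundtrip_preserves_bipartitions_and_lengths(self):
        import dendropy

        rng = np.random.default_rng(3)
        _, dm = random_additive(8, rng)
        tree = neighbor_joining(dm)
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        mine = tree.leaf_distances()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(mine.labels):
            for j, b in enumerate(mine.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        mine.d[i, j], abs=1e-4
                    )


class TestBootstrap:
    def test_forced_cherry_has_full_support(self):
        rng = np.random.default_rng(0)
        alpha = "ACDEFGHIKL"
        far = {f"x{i}": "".join(rng.choice(list(alpha), 60)) for i in range(3)}
        twin = "".join(rng.choice(list(alpha), 60))
        a = aln({"t1": twin, "t2": twin, **far})
        tree = bootstrap_support(a, n_reps=50, seed=1)
        support = {frozenset(c[:2]): c[2] for c in tree.cherries()}
        assert support[frozenset(["t1", "t2"])] == 100.0

    def test_same_seed_same_supports(self, bundle):
        t1 = bootstrap_support(bundle.alignment, n_reps=20, seed=5)
        t2 = bootstrap_support(bundle.alignment, n_reps=20, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_bounded_and_leaf_order_invariant(self, bundle):
        t1 = bootstrap_support(bundle.alignment, n_reps=20, seed=5)
        sides1 = {s: n.support for s, n in t1.bipartitions().items()}
        assert all(0 <= v <= 100 for v in sides1.values())
        shuffled = Alignment(list(reversed(bundle.alignment.records)))
        t2 = bootstrap_support(shuffled, n_reps=20, seed=5)
        sides2 = set(t2.bipartitions())
        assert set(sides1) == sides2  # same NJ topology regardless of input order


class TestSisterPairs:
    def _toy(self):
        # ((Cp1,At1)99, ((Cp2,Os1)80, At2))
        c1 = TreeNode(length=0.2, support=99.0, children=[
            TreeNode(name="Cp1", length=0.1), TreeNode(name="At1", length=0.1)])
        c2 = TreeNode(length=0.2, support=80.0, children=[
            TreeNode(name="Cp2", length=0.1), TreeNode(name="Os1", length=0.1)])
        inner = TreeNode(length=0.2, support=95.0, children=[
            c2, TreeNode(name="At2", length=0.3)])
        return PhyloTree(TreeNode(children=[c1, inner, TreeNode(name="out", length=0.5)]))

    SPECIES = {"Cp1": "Cp", "Cp2": "Cp", "At1": "At", "At2": "At",
               "Os1": "Os", "out": "Zz"}

    def test_threshold_filters_low_support(self):
        pairs = find_sister_pairs(self._toy(), self.SPECIES, 99)
        assert [(p.leaf_a, p.leaf_b, p.support) for p in pairs] == [
            ("At1", "Cp1", 99.0)
        ]

    def test_lower_threshold_admits_both(self):
        pairs = find_sister_pairs(self._toy(), self.SPECIES, 80)
        assert {frozenset((p.leaf_a, p.leaf_b)) for p in pairs} == {
            frozenset(("Cp1", "At1")), frozenset(("Cp2", "Os1")),
        }

    def test_same_species_cherry_ignored(self):
        tree = self._toy()
        species = dict(self.SPECIES, Os1="Cp")  # make Cp2-Os1 a same-species pair
        pairs = find_sister_pairs(tree, species, 50)
        assert {p.leaf_a for p in pairs} == {"At1"}

    def test_unknown_leaf_error(self):
        with pytest.raises(ValueError, match="out"):
            find_sister_pairs(self._toy(), {k: v for k, v in self.SPECIES.items() if k != "out"}, 99)

    def test_study_like_configuration_recovered(self, bundle):
        tree = bootstrap_support(bundle.alignment, n_reps=200, seed=9)
        pairs = find_sister_pairs(tree, bundle.species_map, 95.0)
        cp_at = {
            tuple(sorted((p.leaf_a, p.leaf_b)))
            for p in pairs
            if {p.species_a, p.species_b} == {"Cp", "At"}
        }
        cp_os = [p for p in pairs if {p.species_a, p.species_b} == {"Cp", "Os"}]
        assert cp_at == set(bundle.manifest.cherries)
        assert len(cp_at) == 7
        assert cp_os == []


class TestAssignGroups:
    def _tree(self):
        # ((r1,r2),(r3,f1),f2-out) with r1,r2,r3 references
        left = TreeNode(length=0.1, children=[
            TreeNode(name="r1", length=0.1), TreeNode(name="r2", length=0.1)])
        mid = TreeNode(length=0.1, children=[
            TreeNode(name="r3", length=0.1), TreeNode(name="f1", length=0.1)])
        return PhyloTree(TreeNode(children=[left, mid, TreeNode(name="f2", length=0.4)]))

    def test_homogeneous_clade_inherited(self):
        groups = assign_groups(self._tree(), {"r1": "II", "r2": "II", "r3": "II"})
        assert groups["f1"] == "II"
        assert groups["f2"] == "II"

    def test_mixed_clade_unplaced(self):
        groups = assign_groups(self._tree(), {"r1": "I", "r2": "I", "r3": "III"})
        assert groups["f1"] == "III"  # smallest enclosing homogeneous clade
        assert groups["f2"] == "unplaced"  # root-level mix of I and III

    def test_reference_leaves_keep_their_group(self):
        groups = assign_groups(self._tree(), {"r1": "I", "r2": "I", "r3": "II"})
        assert groups["r3"] == "II"
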