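"""Distance-based phylogenetics: p/Poisson distances, neighbor joining with
deterministic tie-breaking, Felsenstein bootstrap support, cross-species
sister-pair (cherry) detection, and reference-guided group assignment.

Trees are unrooted; internally they are stored rooted at the final
neighbor-joining join (a degree-3 node), and all support/cherry logic works
on bipartitions so the arbitrary rooting never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord

logger = logging.getLogger("arffam")

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "SisterPair",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "find_sister_pairs",
    "assign_groups",
]

GAP = "-"


@dataclass
class Alignment:
    """A protein multiple sequence alignment (gap character '-')."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValueError("alignment needs at least 3 sequences")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq)

    def to_array(self) -> np.ndarray:
        """(n_taxa, n_columns) uint8 matrix of residue byte codes."""
        return np.frombuffer(
            "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.records), self.n_columns)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns resampled with replacement."""
        cols = rng.integers(0, self.n_columns, self.n_columns)
        arr = self.to_array()[:, cols]
        recs = [
            SequenceRecord(r.id, arr[i].tobytes().decode("ascii"), "protein")
            for i, r in enumerate(self.records)
        ]
        return Alignment(recs)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(self.d < 0) or np.any(np.diag(self.d) != 0):
            raise ValueError("distances must be >= 0 with zero diagonal")


def _masked_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (shared ungapped columns, mismatches among them)."""
    gap = np.uint8(ord(GAP))
    valid = arr != gap
    both = valid[:, None, :] & valid[None, :, :]
    shared = both.sum(axis=2)
    diff = (arr[:, None, :] != arr[None, :, :]) & both
    return shared, diff.sum(axis=2)


def pairwise_distance(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise-deletion distances.

    p-distance = mismatches / shared ungapped columns; the Poisson
    correction -ln(1 - p) accounts for multiple hits. Poisson is undefined
    at p = 1 (raises, suggesting p_distance).
    """
    if model not in {"p_distance", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    arr = aln.to_array()
    shared, mism = _masked_counts(arr)
    np.fill_diagonal(shared, 2)  # exempt the diagonal from 0/0 and the check below
    if np.any(shared < 2):
        i, j = np.argwhere(shared < 2)[0]
        raise ValueError(
            f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share fewer than "
            "2 ungapped columns"
        )
    p = mism / shared
    np.fill_diagonal(p, 0.0)
    if model == "p_distance":
        d = p
    else:
        if np.any(p >= 1.0):
            raise ValueError(
                "p-distance of 1 cannot be Poisson-corrected; "
                "use model='p_distance'"
            )
        d = -np.log1p(-p)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(list(aln.ids), d)


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap % on the edge to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return out


class PhyloTree:
    """Unrooted tree stored with an arbitrary degree-3 root."""

    def __init__(self, root: TreeNode):
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.{decimals}f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.{decimals}f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal bipartitions, canonicalized as the side not containing
        the lexicographically smallest leaf; mapped to the child node whose
        parent edge induces them."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out[side] = node
            return below

        walk(self.root)
        return out

    def cherries(self) -> list[tuple[str, str, float | None]]:
        """Leaf pairs attached to a common internal node (cherries of the
        unrooted tree), with the support of the separating edge."""
        n = len(self.leaf_names)
        found: list[tuple[str, str, float | None]] = []
        for side, node in self.bipartitions().items():
            pair = side if len(side) == 2 else None
            if pair is None and n - len(side) == 2:
                pair = frozenset(self.leaf_names) - side
            if pair is not None:
                a, b = sorted(pair)
                found.append((a, b, node.support))
        return sorted(found)

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.name]: 0.0}
            below: dict[int, float] = {}
            for child in node.children:
                sub = {k: v + child.length for k, v in walk(child).items()}
                for i, di in sub.items():
                    for j, dj in below.items():
                        d[i, j] = d[j, i] = di + dj
                below.update(sub)
            return below

        walk(self.root)
        return DistanceMatrix(names, d)


def _min_leaf_key(node: TreeNode) -> str:
    return min(leaf.name for leaf in node.leaves())


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(i,j) = (m-2) d(i,j) - R_i - R_j is
    joined; ties are broken by the lexicographically smallest (sorted) pair
    of cluster labels, where a cluster's label is its smallest leaf id.
    Negative branch-length estimates are clamped to zero and logged.
    """
    m = len(dm.labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    keys: list[str] = list(dm.labels)

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.debug("NJ: negative branch length %.3g at %s clamped", x, context)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        dij = D[i, j]
        vi = clamp(0.5 * dij + (R[i] - R[j]) / (2 * (m - 2)), keys[i])
        vj = clamp(dij - vi, keys[j])
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = vi, vj
        new = TreeNode(children=[child_i, child_j])
        new_key = min(keys[i], keys[j])
        new_row = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # terminal star join of the last three clusters
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc), keys[0])
    b.length = clamp(0.5 * (dab + dbc - dac), keys[1])
    c.length = clamp(0.5 * (dac + dbc - dab), keys[2])
    return PhyloTree(TreeNode(children=[a, b, c]))


def bootstrap_support(
    aln: Alignment,
    model: str = "poisson",
    n_reps: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree on the full alignment with Felsenstein bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each original
    internal bipartition's support is the percentage of replicate trees
    containing it. Degenerate replicates (no phylogenetic signal or
    saturated distances) are skipped with a log message, never fatal.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(pairwise_distance(aln, model))
    biparts = tree.bipartitions()
    counts = {side: 0 for side in biparts}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            rep_dm = pairwise_distance(rep, model)
        except ValueError as exc:
            logger.info("bootstrap: replicate skipped (%s)", exc)
            continue
        if np.all(rep_dm.d == 0):
            logger.info("bootstrap: replicate skipped (no variation)")
            continue
        used += 1
        rep_sides = neighbor_joining(rep_dm).bipartitions().keys()
        for side in counts.keys() & rep_sides:
            counts[side] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    for side, node in biparts.items():
        node.support = 100.0 * counts[side] / used
    return tree


@dataclass
class SisterPair:
    leaf_a: str
    leaf_b: str
    species_a: str
    species_b: str
    support: float


def find_sister_pairs(
    tree: PhyloTree,
    species_map: dict[str, str],
    min_support: float = 99.0,
) -> list[SisterPair]:
    """Cross-species cherries with bootstrap support >= min_support.

    A sister pair is a cherry (two leaves joined to the same internal node)
    whose leaves belong to two different species in ``species_map``.
    """
    for leaf in tree.leaf_names:
        if leaf not in species_map:
            raise ValueError(f"leaf {leaf!r} missing from species map")
    pairs = []
    for a, b, support in tree.cherries():
        sp_a, sp_b = species_map[a], species_map[b]
        if sp_a == sp_b:
            continue
        if support is None or support >= min_support:
            pairs.append(SisterPair(a, b, sp_a, sp_b, support if support is not None else float("nan")))
    return pairs


def assign_groups(
    tree: PhyloTree,
    reference_groups: dict[str, str],
) -> dict[str, str]:
    """Assign each unlabelled leaf the group of its smallest enclosing clade
    whose reference members are group-homogeneous; "unplaced" otherwise.

    The unrooted tree is rooted at its stored degree-3 node; for each focal
    leaf, ancestors are walked tipward-to-rootward and the first one whose
    reference-leaf set is non-empty decides: homogeneous -> that group,
    mixed -> unplaced.
    """
    parents: dict[int, TreeNode] = {}

    def index(node: TreeNode) -> None:
        for child in node.children:
            parents[id(child)] = node
            index(child)

    index(tree.root)
    leaves = {n.name: n for n in tree.root.leaves()}
    out: dict[str, str] = {}
    for name, node in leaves.items():
        if name in reference_groups:
            out[name] = reference_groups[name]
            continue
        label = "unplaced"
        current = node
        while id(current) in parents:
            current = parents[id(current)]
            ref_here = {
                reference_groups[l.name]
                for l in current.leaves()
                if l.name in reference_groups
            }
            if len(ref_here) == 1:
                label = next(iter(ref_here))
                break
            if len(ref_here) > 1:
                break
        out[name] = label
    return out
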