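"""Neighbor-Joining trees, bootstrap support, concatenation and monophyly.

The agglomeration follows Saitou & Nei with the Studier–Keppler criterion
Q(i,j) = (n-2) d(i,j) - r(i) - r(j); at each step the pair minimising Q is
joined, with ties broken deterministically in favour of the lowest index pair
under the matrix's row order.  Negative branch-length estimates are clamped to
zero (display convention of the common tree software) and the clamped deficit
is recorded on the tree.  Trees are unrooted; dendropy carries the topology,
branch lengths and Newick serialisation.

Bootstrap support resamples alignment columns with replacement, rebuilds the
NJ tree per replicate, and reports for each internal edge of the original tree
the percentage of replicates whose tree contains the same leaf bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .distances import AlignedBlock, DistanceMatrix, DistanceModel, distance_matrix
from .errors import ComputationError, DataValidationError


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    tree: dendropy.Tree
    n_clamped: int = 0
    clamped_total: float = 0.0  # total negative length clamped away
    support: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.edges() if e.tail_node is not None
        )

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial leaf bipartitions, each as its anchor-free side."""
        return frozenset(_splits(self.tree))

    def newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".8g",
            ).strip()
            + "\n"
        )


def _leafset(node, cache: dict) -> frozenset[str]:
    if node in cache:
        return cache[node]
    if node.is_leaf():
        out = frozenset([node.taxon.label])
    else:
        out = frozenset().union(*(_leafset(c, cache) for c in node.child_nodes()))
    cache[node] = out
    return out


def _splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Map each non-trivial bipartition to its head node.

    Bipartitions are normalised to the side *not* containing the
    lexicographically smallest leaf label, so both orientations compare equal.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if not leaves:
        return {}
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    n = len(leaves)
    cache: dict = {}
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = _leafset(node, cache)
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        if anchor in side:
            side = all_leaves - side
        out[side] = node
    return out


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-Joining tree from a complete (no undefined entries) matrix."""
    if matrix.has_undefined:
        pairs = matrix.undefined_pairs()
        raise ComputationError(
            f"distance matrix has {len(pairs)} undefined pair(s), e.g. "
            f"{pairs[0][0]}–{pairs[0][1]}; cannot build NJ tree"
        )
    n0 = matrix.n
    if n0 < 2:
        raise DataValidationError("NJ requires at least 2 taxa")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in matrix.accession_ids:
        taxon = tns.new_taxon(label=name)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    D = matrix.values.astype(float).copy()
    n_clamped = 0
    clamped_total = 0.0

    def clamp(v: float) -> float:
        nonlocal n_clamped, clamped_total
        if v < 0.0:
            n_clamped += 1
            clamped_total += -v
            return 0.0
        return v

    if n0 == 2:
        root = dendropy.Node()
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        half = clamp(float(D[0, 1])) / 2.0
        nodes[0].edge.length = half
        nodes[1].edge.length = half
        tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
        tree.is_rooted = False
        return PhyloTree(tree=tree, n_clamped=n_clamped, clamped_total=clamped_total)

    active = list(range(n0))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = math.inf
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-15:  # strict improvement => lowest-index tie rule
                    best_q = q
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        d_ij = sub[a, b]
        v_i = 0.5 * d_ij + (r[a] - r[b]) / (2.0 * (m - 2))
        v_j = d_ij - v_i
        new_node = dendropy.Node()
        new_node.add_child(nodes[i])
        new_node.add_child(nodes[j])
        nodes[i].edge.length = clamp(v_i)
        nodes[j].edge.length = clamp(v_j)
        # distances from the new internal node to every remaining cluster
        new_row = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (D[i, c] + D[j, c] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new_node)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, v in ((i, vi), (j, vj), (k, vk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(v)
    else:  # exactly 2 active clusters remain (n0 == 3 never lands here)
        i, j = active
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        half = clamp(float(D[i, j])) / 2.0
        nodes[i].edge.length = half
        nodes[j].edge.length = half

    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = False
    return PhyloTree(tree=tree, n_clamped=n_clamped, clamped_total=clamped_total)


@dataclass(frozen=True)
class ConcatenatedAlignment:
    """Markers joined side-by-side into one supermatrix."""

    block: AlignedBlock
    offsets: Mapping[str, tuple[int, int]]  # marker_id -> [start, end)

    @property
    def length(self) -> int:
        return self.block.length


def concatenate(
    blocks: Mapping[str, AlignedBlock], marker_order: Sequence[str] | None = None
) -> ConcatenatedAlignment:
    """Join per-marker aligned blocks in the stated order, recording offsets."""
    if not blocks:
        raise DataValidationError("no blocks to concatenate")
    order = list(marker_order) if marker_order is not None else list(blocks)
    missing = [m for m in order if m not in blocks]
    if missing:
        raise DataValidationError(f"marker(s) not provided: {', '.join(missing)}")
    first = blocks[order[0]]
    ids = first.accession_ids
    id_set = set(ids)
    for mid in order[1:]:
        other = set(blocks[mid].accession_ids)
        if other != id_set:
            only_a = sorted(id_set - other)
            only_b = sorted(other - id_set)
            raise DataValidationError(
                f"accession sets differ between {order[0]!r} and {mid!r}: "
                f"missing {only_a or '-'}, extra {only_b or '-'}"
            )
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    parts: dict[str, list[str]] = {aid: [] for aid in ids}
    for mid in order:
        blk = blocks[mid]
        offsets[mid] = (pos, pos + blk.length)
        pos += blk.length
        for aid in ids:
            parts[aid].append(blk.sequence(aid))
    joined = AlignedBlock(
        accession_ids=ids,
        sequences=tuple("".join(parts[aid]) for aid in ids),
    )
    return ConcatenatedAlignment(block=joined, offsets=offsets)


def bootstrap_support(
    alignment: AlignedBlock | ConcatenatedAlignment,
    model: DistanceModel | str = DistanceModel.K2P,
    replicates: int = 1000,
    seed: int = 0,
    gamma_shape: float | None = None,
) -> PhyloTree:
    """NJ tree of the data with per-edge bootstrap support percentages.

    Columns of the (concatenated) alignment are resampled with replacement;
    support for each internal edge of the original tree is the percentage of
    replicate trees containing the same leaf bipartition.  Replicates whose
    resampled matrix is undefined (saturation) contribute no bipartitions but
    stay in the denominator.
    """
    if replicates < 1:
        raise DataValidationError(f"replicates must be >= 1, got {replicates}")
    block = alignment.block if isinstance(alignment, ConcatenatedAlignment) else alignment
    base = nj_tree(distance_matrix(block, model, gamma_shape))
    targets = _splits(base.tree)
    counts = {split: 0 for split in targets}
    rng = np.random.default_rng(seed)
    cols = [
        tuple(seq[i] for seq in block.sequences) for i in range(block.length)
    ]
    for _ in range(replicates):
        idx = rng.integers(0, block.length, size=block.length)
        resampled = AlignedBlock(
            accession_ids=block.accession_ids,
            sequences=tuple(
                "".join(cols[i][row] for i in idx) for row in range(block.n)
            ),
        )
        try:
            rep_tree = nj_tree(distance_matrix(resampled, model, gamma_shape))
        except ComputationError:
            continue
        rep_splits = _splits(rep_tree.tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    for split, node in targets.items():
        node.label = str(int(round(support[split])))
    base.support = support
    return base


def is_monophyletic(tree: PhyloTree, leaf_set) -> bool:
    """True iff some edge of the unrooted tree separates leaf_set from the rest."""
    group = frozenset(leaf_set)
    if not group:
        raise DataValidationError("empty leaf set")
    leaves = tree.leaf_labels
    unknown = group - leaves
    if unknown:
        raise DataValidationError(f"unknown leaf label(s): {', '.join(sorted(unknown))}")
    n = len(leaves)
    if len(group) <= 1 or len(group) >= n - 1:
        return True  # singletons, full set, and (n-1)-sets are induced trivially
    splits = _splits(tree.tree)
    return group in splits or (leaves - group) in splits


def write_newick(tree: PhyloTree, path: str | Path) -> Path:
    out = Path(path)
    out.write_text(tree.newick(), encoding="utf-8", newline="\n")
    return out


def read_newick(path: str | Path) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise DataValidationError(f"malformed Newick in {path}: {exc}") from exc
    dtree.is_rooted = False
    return PhyloTree(tree=dtree)
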