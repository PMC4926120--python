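"""Neighbour-joining trees with nonparametric bootstrap support.

The agglomeration is the classic Saitou-Nei scheme on a K2P distance matrix:
at each step the pair minimising

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined.  Ties are broken deterministically by the lowest (row, column)
index pair in the current matrix order, which follows the input label order.
Negative branch lengths are clamped to zero with a warning.  Trees are
unrooted (the seed node has degree 3); Newick serialisation and parsing go
through dendropy, with bootstrap supports written as internal-node labels.

Bootstrap resamples alignment columns with replacement, rebuilds the K2P
matrix and the NJ tree per replicate, and reports for every internal edge of
the original tree the percentage of replicates containing the same leaf
bipartition.  A fixed seed gives identical supports run-to-run.
"""

from __future__ import annotations

import warnings
from typing import Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix, pairwise_matrix
from .errors import TreeError
from .seqio import Alignment, SeqRecord

Tree = dendropy.Tree


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Build an unrooted NJ tree from a distance matrix.

    Requires at least 3 labels and no missing (nan) entries.
    """
    n = len(m.labels)
    if n < 3:
        raise TreeError("neighbour joining requires at least 3 taxa")
    if np.isnan(m.values).any():
        bad = [
            (m.labels[i], m.labels[j])
            for i, j in zip(*np.where(np.isnan(m.values))) if i < j
        ]
        raise TreeError(f"distance matrix has missing entries: {bad[:5]}")

    taxa = dendropy.TaxonNamespace(m.labels)
    nodes = []
    for lab in m.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    D = m.values.astype(float).copy()
    active = list(range(n))
    clamped = 0

    def _join(i_pos: int, j_pos: int) -> None:
        nonlocal D, active, clamped
        i, j = active[i_pos], active[j_pos]
        r = len(active)
        row_sums = D[np.ix_(active, active)].sum(axis=1)
        d_ij = D[i, j]
        li = 0.5 * d_ij + (row_sums[i_pos] - row_sums[j_pos]) / (2.0 * (r - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            if length < 0:
                clamped += 1
                length = 0.0
            child.edge.length = length
            parent.add_child(child)
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        new_index = D.shape[0] - 1
        active[:] = [a for a in active if a not in (i, j)] + [new_index]

    while len(active) > 3:
        sub = D[np.ix_(active, active)]
        r = len(active)
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: first (i, j), i < j, achieving the minimum
        qmin = q.min()
        i_pos, j_pos = next(
            (a, b) for a in range(r) for b in range(a + 1, r)
            if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin))
        )
        _join(i_pos, j_pos)

    # resolve the final three nodes around one internal node (unrooted, degree 3)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            clamped += 1
            length = 0.0
        nodes[idx].edge.length = length
        center.add_child(nodes[idx])
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch length(s) clamped to 0")
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return tree


def tree_length(t: Tree) -> float:
    """Sum of all branch lengths."""
    return sum(e.length or 0.0 for e in t.edges())


def bipartitions(t: Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each normalised to the side that does
    not contain the lexicographically smallest leaf label."""
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in t.preorder_node_iter():
        if node is t.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if len(side) >= 2 and len(leaves) - len(side) >= 2:
            out.add(side)
    return out


def _resample_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    idx = rng.integers(0, aln.length, size=aln.length)
    records = [
        SeqRecord(id=r.id, species=r.species,
                  sequence="".join(r.sequence[i] for i in idx))
        for r in aln
    ]
    return Alignment(records)


def bootstrap_support(
    aln: Alignment,
    reps: int = 1000,
    seed: Optional[int] = None,
    deletion: str = "pairwise",
) -> Tree:
    """NJ tree of the alignment with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; support for each
    internal edge of the original tree is the percentage of (successful)
    replicates whose NJ tree contains the same bipartition.  Replicates whose
    resampled matrix contains a saturated pair are skipped with a warning.
    """
    if reps < 1:
        raise TreeError("bootstrap requires reps >= 1")
    rng = np.random.default_rng(seed)
    base_matrix = pairwise_matrix(aln, deletion=deletion)
    tree = neighbor_joining(base_matrix)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    used = 0
    for _ in range(reps):
        resampled = _resample_columns(aln, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix = pairwise_matrix(resampled, deletion=deletion)
        if np.isnan(matrix.values).any():
            warnings.warn("bootstrap replicate with saturated distances skipped")
            continue
        rep_bps = bipartitions(neighbor_joining(matrix))
        used += 1
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if used == 0:
        raise TreeError("all bootstrap replicates failed (saturated distances)")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if side in counts:
            node.label = str(round(100.0 * counts[side] / used))
    return tree


def to_newick(t: Tree) -> str:
    """Newick text with branch lengths and supports as internal-node labels."""
    return t.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def from_newick(text: str) -> Tree:
    """Parse Newick text (inverse of :func:`to_newick` up to topology)."""
    return dendropy.Tree.get(
        data=text, schema="newick",
        preserve_underscores=True,
    )


def root_with_outgroup(t: Tree, outgroup: str) -> Tree:
    """Root a copy of the tree on the edge leading to ``outgroup`` (display only)."""
    rooted = t.clone(depth=1)
    node = rooted.find_node_with_taxon_label(outgroup)
    if node is None:
        raise TreeError(f"outgroup {outgroup!r} not found in tree")
    rooted.to_outgroup_position(node, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted
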