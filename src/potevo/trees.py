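"""Neighbor-joining tree construction, bootstrap and interior-branch support.

The tree container is a :class:`dendropy.Tree` (unrooted trees carry a
trifurcating seed node), so Newick serialization and bipartition
bookkeeping come from dendropy; the NJ algorithm itself and the support
statistics are implemented here.

Support conventions
-------------------
* ``bootstrap_support`` is the fraction of site-resampled replicates
  whose NJ tree contains the same bipartition, on [0, 1].
* The interior-branch test treats each interior edge length as
  approximately normal: the edge's standard error is the standard
  deviation of its length across bootstrap replicates (length 0 where
  the bipartition is absent from a replicate), and the confidence
  probability is the one-sided normal probability that the true length
  exceeds zero, ``Phi(length / se)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import norm

from .distances import (
    DistanceMatrix,
    Model,
    SaturationError,
    complete_deletion,
    distance_matrix,
)
from .seqio import Alignment, SequenceRecord

__all__ = [
    "SupportReport",
    "neighbor_joining",
    "bootstrap_support",
    "interior_branch_test",
    "bipartition_supports",
]


@dataclass
class SupportReport:
    """Support statistics for one interior edge (bipartition)."""

    bipartition: frozenset[str]  # taxa on the smaller/child side of the edge
    length: float
    bootstrap_support: float | None = None  # fraction of replicates, [0,1]
    branch_se: float | None = None
    confidence_probability: float | None = None


def _clamp_pair(v_i: float, v_j: float) -> tuple[float, float]:
    """Clamp a negative NJ branch length to 0, moving the deficit onto
    the adjacent (sibling) branch, then floor that at 0 too."""
    if v_i < 0.0:
        v_j += v_i
        v_i = 0.0
    if v_j < 0.0:
        v_i += v_j
        v_j = 0.0
    return max(v_i, 0.0), max(v_j, 0.0)


def neighbor_joining(
    dm: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a distance matrix.

    At each step the pair (i, j) minimizing
    ``Q(i,j) = (r - 2) D(i,j) - R_i - R_j`` (with ``R_i = sum_k D(i,k)``)
    is joined; ties broken by the lowest (i, j) index pair in the current
    node ordering, so the algorithm is deterministic for a given input
    order.  Branch lengths come from the standard two-point formulas;
    negative lengths are clamped to zero with the deficit moved to the
    sibling branch.  Returns an unrooted tree (trifurcating seed node)
    for >= 4 taxa; exactly 3 taxa give the unique star with closed-form
    lengths.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")

    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(list(dm.ids))
    nodes: list[dendropy.Node] = []
    for taxon_id in dm.ids:
        taxon = taxon_namespace.get_taxon(taxon_id)
        if taxon is None:
            taxon = taxon_namespace.new_taxon(taxon_id)
        nodes.append(dendropy.Node(taxon=taxon))

    D = dm.d.astype(float).copy()

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima: argmin on the upper triangle scans
        # row-major, which is exactly lexicographic (i, j) order
        iu = np.triu_indices(r, k=1)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])

        v_i = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        v_j = D[i, j] - v_i
        v_i, v_j = _clamp_pair(v_i, v_j)

        parent = dendropy.Node()
        nodes[i].edge.length = v_i
        nodes[j].edge.length = v_j
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        D_next = np.empty((r - 1, r - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = d_new[keep]
        D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        D = D_next
        nodes = [nodes[x] for x in keep] + [parent]

    # join the final three nodes at a trifurcating root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    root = dendropy.Node()
    for node, length in zip(nodes, lengths):
        node.edge.length = max(length, 0.0)
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
    tree.is_rooted = False
    return tree


def _interior_edges(tree: dendropy.Tree) -> list[dendropy.Edge]:
    tree.encode_bipartitions()
    return [
        e
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None and not e.bipartition.is_trivial()
    ]


def _edge_taxa(edge: dendropy.Edge, tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(
        leaf.taxon.label for leaf in edge.head_node.leaf_iter()
    )


def _replicate_trees(
    aln: Alignment,
    model: Model,
    n_reps: int,
    seed: int | np.random.Generator,
    taxon_namespace: dendropy.TaxonNamespace,
) -> tuple[list[dendropy.Tree], int]:
    """NJ trees from column-resampled replicates; returns (trees, n_dropped).

    Replicates whose resampled alignment contains a saturated pair are
    dropped and counted; more than 20% dropped is an error.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    core = complete_deletion(aln)
    mat = np.array([list(rec.seq) for rec in core.records])
    trees: list[dendropy.Tree] = []
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, core.length, size=core.length)
        resampled = Alignment(
            records=tuple(
                SequenceRecord(id=rec.id, seq="".join(row[cols]))
                for rec, row in zip(core.records, mat)
            )
        )
        try:
            dm = distance_matrix(resampled, model=model, deletion="complete")
        except SaturationError:
            dropped += 1
            continue
        tree = neighbor_joining(dm, taxon_namespace=taxon_namespace)
        tree.encode_bipartitions()
        trees.append(tree)
    if dropped > 0.2 * n_reps:
        raise SaturationError(
            f"{dropped}/{n_reps} bootstrap replicates dropped due to "
            f"saturated pairs"
        )
    return trees, dropped


def bootstrap_support(
    aln: Alignment,
    model: Model = "K2P",
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[dendropy.Tree, list[SupportReport]]:
    """NJ tree with bootstrap support from site resampling.

    Columns of the (complete-deletion) alignment are resampled with
    replacement *n_reps* times; support for each interior edge of the
    full-data tree is the fraction of replicate trees containing the
    same bipartition.  Supports are attached to the tree as internal
    node labels (percent, one decimal) and returned on [0, 1] in the
    reports.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    core = complete_deletion(aln)
    dm = distance_matrix(core, model=model, deletion="complete")
    tree = neighbor_joining(dm)
    tns = tree.taxon_namespace
    reps, _ = _replicate_trees(aln, model, n_reps, seed, tns)
    rep_splits = [
        {e.bipartition.split_bitmask for e in _interior_edges(t)} for t in reps
    ]
    reports: list[SupportReport] = []
    for edge in _interior_edges(tree):
        mask = edge.bipartition.split_bitmask
        support = (
            sum(mask in s for s in rep_splits) / len(rep_splits)
            if rep_splits
            else 0.0
        )
        edge.head_node.label = f"{100.0 * support:.1f}"
        reports.append(
            SupportReport(
                bipartition=_edge_taxa(edge, tree),
                length=float(edge.length),
                bootstrap_support=support,
            )
        )
    return tree, reports


def bipartition_supports(reports: list[SupportReport]) -> dict[frozenset[str], float]:
    """Map bipartition (child-side taxa) -> bootstrap support."""
    return {r.bipartition: r.bootstrap_support for r in reports}


def interior_branch_test(
    aln: Alignment,
    tree: dendropy.Tree | None = None,
    model: Model = "K2P",
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[SupportReport]:
    """Bootstrap z-test that each interior branch has positive length.

    For every interior edge of *tree* (built from the full data if not
    given), the edge length is collected across bootstrap replicates
    (0 when the bipartition is absent); ``branch_se`` is the standard
    deviation of those lengths and the confidence probability is
    ``Phi(length / branch_se)``.  A zero-length edge with zero SE gets
    probability 0.5 by convention; a positive edge with zero SE gets 1.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    core = complete_deletion(aln)
    if tree is None:
        dm = distance_matrix(core, model=model, deletion="complete")
        tree = neighbor_joining(dm)
    tns = tree.taxon_namespace
    reps, _ = _replicate_trees(aln, model, n_reps, seed, tns)
    rep_lengths: list[dict[int, float]] = [
        {e.bipartition.split_bitmask: float(e.length) for e in _interior_edges(t)}
        for t in reps
    ]
    reports: list[SupportReport] = []
    for edge in _interior_edges(tree):
        mask = edge.bipartition.split_bitmask
        lengths = np.array([d.get(mask, 0.0) for d in rep_lengths])
        se = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
        length = float(edge.length)
        if se == 0.0:
            conf = 0.5 if length == 0.0 else 1.0
        else:
            conf = float(norm.cdf(length / se))
        support = (
            float(np.mean([mask in d for d in rep_lengths]))
            if rep_lengths
            else 0.0
        )
        reports.append(
            SupportReport(
                bipartition=_edge_taxa(edge, tree),
                length=length,
                bootstrap_support=support,
                branch_se=se,
                confidence_probability=conf,
            )
        )
    return reports
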