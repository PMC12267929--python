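"""Distance trees for synthetic validation and comparison of organellar trees.

Maximum-likelihood inference is deliberately out of scope: this module
builds simple neighbor-joining trees from p-distances for round-trip tests
of the synthetic generator, and consumes externally inferred Newick trees
for congruence analysis (Robinson-Foulds distance, tanglegram crossings,
polytomy and support summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .errors import ConfigurationError, TreeError
from .mdc import _ACGT  # unambiguous-base codes
from .seqio import Alignment, write_tree


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ConfigurationError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ConfigurationError("distance matrix must be symmetric")
        if np.diag(m).any():
            raise ConfigurationError("diagonal must be zero")
        if (m < 0).any():
            raise ConfigurationError("distances must be nonnegative")


def p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise p-distances (mismatches / compared sites, pairwise deletion)."""
    m = alignment.matrix
    n = m.shape[0]
    if n < 3:
        raise ConfigurationError("need >= 3 sequences")
    ok = np.isin(m, _ACGT)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = ok[i] & ok[j]
        comp = int(both.sum())
        if comp == 0:
            raise ConfigurationError(
                f"pair ({alignment.sample_ids[i]}, {alignment.sample_ids[j]}) "
                "has no compared sites"
            )
        d[i, j] = d[j, i] = ((m[i] != m[j]) & both).sum() / comp
    return DistanceMatrix(list(alignment.sample_ids), d)


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining; negative branch lengths are clamped to zero with
    the deficit shifted onto the sister edge."""
    n = len(dist.taxa)
    if n < 3:
        raise ConfigurationError("need >= 3 taxa")
    ns = dendropy.TaxonNamespace(dist.taxa)
    nodes = []
    for label in dist.taxa:
        nd = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(nd)
    d = dist.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        na = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (na - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (na - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # new row for the joined node
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = max(ln, 0.0)
    else:  # two clusters remain
        i, j = active
        root.add_child(nodes[i])
        nodes[i].edge.length = d[i, j] / 2
        root.add_child(nodes[j])
        nodes[j].edge.length = d[i, j] / 2
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def _common_namespace(t1: dendropy.Tree, t2: dendropy.Tree):
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=write_tree(t1), schema="newick", taxon_namespace=ns,
        suppress_internal_node_taxa=True,
    )
    b = dendropy.Tree.get(
        data=write_tree(t2), schema="newick", taxon_namespace=ns,
        suppress_internal_node_taxa=True,
    )
    a.is_rooted = False
    b.is_rooted = False
    return a, b


def _leaf_set(t: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in t.leaf_node_iter()}


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Robinson-Foulds symmetric difference of nontrivial bipartitions,
    plus its normalization by 2(n-3)."""
    s1, s2 = _leaf_set(t1), _leaf_set(t2)
    if s1 != s2:
        raise TreeError(
            f"leaf sets differ: only in first {sorted(s1 - s2)}, "
            f"only in second {sorted(s2 - s1)}"
        )
    a, b = _common_namespace(t1, t2)
    rf = int(treecompare.symmetric_difference(a, b))
    n = len(s1)
    denom = 2 * (n - 3)
    normalized = rf / denom if denom > 0 else 0.0
    return rf, normalized


def _leaf_order(t: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in t.leaf_node_iter()]


def count_crossings(order1: list[str], order2: list[str]) -> int:
    """Line crossings between matched leaves of two linear leaf orders."""
    pos2 = {label: i for i, label in enumerate(order2)}
    seq = [pos2[label] for label in order1 if label in pos2]
    inv = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                inv += 1
    return inv


def tanglegram(
    t1: dendropy.Tree, t2: dendropy.Tree, max_sweeps: int = 10
) -> tuple[list[str], list[str], int]:
    """Greedy subtree-rotation heuristic minimizing leaf-line crossings.

    Child orders of both trees are flipped whenever a flip reduces the
    crossing count; sweeps repeat until no improvement.  Deterministic
    given input order.  Returns the two leaf orders and the crossing count.
    """
    if _leaf_set(t1) != _leaf_set(t2):
        raise TreeError("tanglegram requires a shared leaf set")
    a = dendropy.Tree.get(data=write_tree(t1), schema="newick",
                          suppress_internal_node_taxa=True)
    b = dendropy.Tree.get(data=write_tree(t2), schema="newick",
                          suppress_internal_node_taxa=True)

    def crossings() -> int:
        return count_crossings(_leaf_order(a), _leaf_order(b))

    current = crossings()
    for _ in range(max_sweeps):
        improved = False
        for tree in (a, b):
            for node in tree.preorder_internal_node_iter():
                children = list(node.child_nodes())
                if len(children) < 2:
                    continue
                node.set_child_nodes(list(reversed(children)))
                trial = crossings()
                if trial < current:
                    current = trial
                    improved = True
                else:
                    node.set_child_nodes(children)
        if not improved:
            break
    return _leaf_order(a), _leaf_order(b), current


def tree_summary(
    tree: dendropy.Tree, support_threshold: float = 60.0
) -> dict:
    """Polytomy and low-support counts.

    A polytomy is an internal node with more than two children; at the root
    of an unrooted tree three children are the resolved convention, so the
    root counts only beyond three.  A low-support clade is an internal edge
    whose support falls below the threshold.
    """
    polytomies = 0
    low_support = 0
    internal_edges = 0
    root = tree.seed_node
    for node in tree.preorder_internal_node_iter():
        nc = len(node.child_nodes())
        if node is root:
            limit = 3 if nc >= 3 else 2
            if nc > limit:
                polytomies += 1
        elif nc > 2:
            polytomies += 1
        if node is not root:
            internal_edges += 1
            sup = getattr(node, "support", None)
            if sup is not None and sup < support_threshold:
                low_support += 1
    return {
        "polytomies": polytomies,
        "low_support_clades": low_support,
        "internal_edges": internal_edges,
        "support_threshold": support_threshold,
    }


def reroot_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Reroot on the edge subtending the named leaf (for rooted summaries)."""
    t = dendropy.Tree.get(data=write_tree(tree), schema="newick",
                          suppress_internal_node_taxa=True)
    node = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise TreeError(f"outgroup {outgroup!r} not found")
    t.to_outgroup_position(node, update_bipartitions=False)
    return t
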