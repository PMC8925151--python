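"""Distance-based phylogenies: neighbor joining and BIONJ.

Classic NJ (Saitou & Nei agglomeration with the standard rate-corrected Q
criterion) and BIONJ (the variance-weighted variant: each agglomeration picks
the mixing weight lambda in [0, 1] that minimises the variance of the reduced
distance estimates) are implemented over :class:`~repeatarray.distance.DistanceMatrix`
inputs.  Trees are :class:`dendropy.Tree` objects wrapped in
:class:`PhyloTree`; negative branch-length estimates are clamped to zero with
the pre-clamp value logged.  Agglomeration ties are broken on the
lexicographically smallest label pair so runs are reproducible.

The distance need not be metric (the slippage-aware gap costs can violate the
triangle inequality); NJ tolerates that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .distance import DistanceMatrix
from .errors import TreeError

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-10


@dataclass
class PhyloTree:
    """A (possibly rooted) tree over distance-matrix labels."""

    tree: dendropy.Tree
    method: str
    #: (child labels seen from the clamped edge, pre-clamp length) pairs
    clamped: list[tuple[str, float]] = field(default_factory=list)

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    @property
    def is_rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def newick(self) -> str:
        """Newick string, branch lengths with 6 decimals."""
        return self.tree.as_string(
            schema="newick",
            real_value_format_specifier=".6f",
            suppress_rooting=False,
        ).strip()

    def write_newick(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(self.newick() + "\n")

    def ascii(self) -> str:
        return self.tree.as_ascii_plot()


def _clamp(length: float, where: str, log: list[tuple[str, float]]) -> float:
    if length < -1e-9:
        logger.warning("negative branch length %.6g at %s clamped to 0", length, where)
        log.append((where, length))
        return 0.0
    if length < 0:  # float noise: zero silently
        return 0.0
    return length


def nj_tree(m: DistanceMatrix, method: str = "bionj") -> PhyloTree:
    """Agglomerate a distance matrix into an unrooted NJ or BIONJ tree.

    Requires at least three labels and finite entries.  The returned tree is
    unrooted (basal trifurcation).
    """
    if method not in ("nj", "bionj"):
        raise TreeError(f"unknown method {method!r}")
    n = len(m.labels)
    if n < 3:
        raise TreeError(f"need >= 3 taxa, got {n}")
    if not np.all(np.isfinite(m.values)):
        raise TreeError("non-finite entries in distance matrix")

    taxa = dendropy.TaxonNamespace(m.labels)
    clamped: list[tuple[str, float]] = []
    # active-node bookkeeping: dendropy node, tie-break key (min leaf label)
    nodes = {i: dendropy.Node(taxon=taxa.get_taxon(lab)) for i, lab in enumerate(m.labels)}
    keys = {i: lab for i, lab in enumerate(m.labels)}
    D = {
        (i, j): float(m.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    V = dict(D)  # BIONJ variance estimates start equal to the distances

    def d(i, j, M=None):
        M = D if M is None else M
        return 0.0 if i == j else M[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d(i, k) for k in active) for i in active}
        best_q, best_pair = None, None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * d(i, j) - R[i] - R[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if (
                    best_q is None
                    or q < best_q - _TIE_EPS
                    or (abs(q - best_q) <= _TIE_EPS and pair_key < best_key)
                ):
                    best_q, best_pair, best_key = q, (i, j), pair_key
        i, j = best_pair
        dij = d(i, j)
        bi = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        bj = dij - bi
        bi_c = _clamp(bi, keys[i], clamped)
        bj_c = _clamp(bj, keys[j], clamped)
        if method == "bionj":
            vij = d(i, j, V)
            if vij > 0:
                lam = 0.5 + sum(
                    d(j, k, V) - d(i, k, V) for k in active if k not in (i, j)
                ) / (2 * (r - 2) * vij)
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
        else:
            lam = 0.5
        u = dendropy.Node()
        u.add_child(nodes[i])
        nodes[i].edge.length = bi_c
        u.add_child(nodes[j])
        nodes[j].edge.length = bj_c
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            # reduction uses the *unclamped* estimates (estimation, not output)
            D[(min(k, new), max(k, new))] = lam * (d(i, k) - bi) + (1 - lam) * (
                d(j, k) - bj
            )
            V[(min(k, new), max(k, new))] = (
                lam * d(i, k, V) + (1 - lam) * d(j, k, V) - lam * (1 - lam) * vij
                if method == "bionj"
                else 0.0
            )
        nodes[new] = u
        keys[new] = min(keys[i], keys[j])
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    # three-point formulas for the final trifurcation
    xi = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    xj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    xk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    center = dendropy.Node()
    for idx, x in ((i, xi), (j, xj), (k, xk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = _clamp(x, keys[idx], clamped)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree=tree, method=method, clamped=clamped)


def root_tree(t: PhyloTree, outgroup: str, fraction: float = 0.5) -> PhyloTree:
    """Root on the outgroup's pendant branch.

    The root is inserted ``fraction`` of the way along the outgroup's branch
    (from the outgroup side); the outgroup becomes a child of the root.
    Rooting only adds a degree-2 node, so leaf-to-leaf path lengths are
    unchanged.
    """
    if not (0 < fraction < 1):
        raise TreeError("rooting fraction must be in (0, 1)")
    t2 = t.tree.clone(depth=1)
    leaf = t2.find_node_with_taxon_label(outgroup)
    if leaf is None:
        raise TreeError(f"outgroup {outgroup!r} not among leaves")
    pendant = leaf.edge.length or 0.0
    t2.reroot_at_edge(leaf.edge, update_bipartitions=False)
    children = t2.seed_node.child_nodes()
    for c in children:
        if c is leaf:
            c.edge.length = fraction * pendant
        else:
            c.edge.length = (1 - fraction) * pendant
    t2.is_rooted = True
    return PhyloTree(tree=t2, method=t.method, clamped=list(t.clamped))


def robinson_foulds(a: PhyloTree | dendropy.Tree, b: PhyloTree | dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (shared taxon namespace enforced)."""
    ta = a.tree if isinstance(a, PhyloTree) else a
    tb = b.tree if isinstance(b, PhyloTree) else b
    ns = dendropy.TaxonNamespace()
    ta2 = dendropy.Tree.get(data=ta.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
    tb2 = dendropy.Tree.get(data=tb.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
    # compare as unrooted trees: rooting is a degree-2 node, not topology
    ta2.deroot()
    tb2.deroot()
    ta2.encode_bipartitions()
    tb2.encode_bipartitions()
    return treecompare.symmetric_difference(ta2, tb2)


def random_additive_case(
    n_taxa: int,
    rng: np.random.Generator,
    min_len: float = 0.1,
    max_len: float = 1.0,
) -> tuple[DistanceMatrix, dendropy.Tree]:
    """A random unrooted binary tree and its exact additive distance matrix.

    Used to exercise NJ consistency: on an additive matrix with positive
    internal branches, neighbor joining provably recovers the generating
    topology.
    """
    if n_taxa < 4:
        raise TreeError("additive test cases need >= 4 taxa")
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)

    def blen():
        return float(rng.uniform(min_len, max_len))

    center = dendropy.Node()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    for lab in labels[:3]:
        lf = dendropy.Node(taxon=taxa.get_taxon(lab))
        center.add_child(lf)
        lf.edge.length = blen()
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not center]
        e = edges[rng.integers(len(edges))]
        head, tail = e.head_node, e.tail_node
        mid = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(mid)
        old = e.length
        mid.edge.length = old * float(rng.uniform(0.25, 0.75))
        mid.add_child(head)
        head.edge.length = old - mid.edge.length
        lf = dendropy.Node(taxon=taxa.get_taxon(lab))
        mid.add_child(lf)
        lf.edge.length = blen()
    pdm = tree.phylogenetic_distance_matrix()
    vals = np.zeros((n_taxa, n_taxa))
    for i, li in enumerate(labels):
        for j in range(i + 1, n_taxa):
            dist = pdm.patristic_distance(
                taxa.get_taxon(li), taxa.get_taxon(labels[j])
            )
            vals[i, j] = vals[j, i] = dist
    return DistanceMatrix(labels=labels, values=vals), tree
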