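"""Distance matrices, neighbor-joining, bootstrap and tree I/O.

Trees are :class:`dendropy.Tree` objects with branch lengths in expected
substitutions/site; per-edge bootstrap or MCMC supports live in the child
node's ``label`` (the standard internal-node-label position in Newick).
The built-in engine is distance-based NJ — exact on additive matrices —
while trees from external ML software can be imported via Newick and used
interchangeably downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import (
    DistanceError,
    MatrixError,
    RootingError,
    SaturationError,
)
from .msa_io import Alignment
from .snpscan import _matrix

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "midpoint_root",
    "prune_taxa",
    "read_newick",
    "write_newick",
    "tip_labels",
]

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) over ordered taxa."""

    taxa: tuple[str, ...]
    matrix: np.ndarray  # (n, n) float

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.taxa)
        if m.shape != (n, n):
            raise MatrixError(f"matrix shape {m.shape} != ({n},{n})")
        if not np.all(np.isfinite(m)):
            raise MatrixError("non-finite distances")
        if not np.allclose(m, m.T, atol=1e-12):
            raise MatrixError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise MatrixError("nonzero diagonal")

    def distance(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.matrix[i, j])


def pairwise_distance(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """p- or JC69-distances with pairwise deletion of gap/ambiguous sites.

    Sites where either sequence is not an unambiguous A/C/G/T are excluded
    per pair. ``jc69`` applies d = -(3/4) ln(1 - 4p/3) and raises
    :class:`SaturationError` where p >= 3/4.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown distance model {model!r}")
    if aln.n_taxa < 2:
        raise DistanceError("need >=2 taxa")
    mat = _matrix(aln)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp = int(both.sum())
            if comp == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            p = float(((mat[i] != mat[j]) & both).sum()) / comp
            if model == "jc69":
                if p >= 0.75:
                    raise SaturationError(
                        f"JC69 undefined (p={p:.4f} >= 3/4) for pair "
                        f"{aln.taxa[i]!r}, {aln.taxa[j]!r}"
                    )
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(aln.taxa, d)


def _leaf_node(taxon: dendropy.Taxon) -> dendropy.Node:
    node = dendropy.Node(taxon=taxon)
    return node


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Deterministic: Q-ties are broken by the smallest (lexicographic) pair of
    cluster representative labels. Negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch, preserving
    the pair's path length.
    """
    taxa = dm.taxa
    n = len(taxa)
    if n < 2:
        raise MatrixError("need >=2 taxa")
    tns = dendropy.TaxonNamespace(list(taxa))
    nodes: list[dendropy.Node] = [
        _leaf_node(tns.get_taxon(t)) for t in taxa
    ]
    if n == 2:
        root = dendropy.Node()
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        nodes[0].edge.length = float(dm.matrix[0, 1])
        nodes[1].edge.length = 0.0
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return tree

    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.matrix
    reps = list(taxa) + [""] * n  # representative label per cluster
    active = list(range(n))
    next_idx = n

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        q = np.minimum(q, q.T)  # exact symmetry despite float non-associativity
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] == qmin:
                    key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            D[next_idx, k] = D[k, next_idx] = 0.5 * (D[i, k] + D[j, k] - dij)
        reps[next_idx] = min(reps[i], reps[j])
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1
        if next_idx >= size:  # pragma: no cover - sizing guard
            D = np.pad(D, ((0, size), (0, size)))
            reps.extend([""] * size)
            size *= 2

    root = dendropy.Node()
    a, b, c = active
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    root.add_child(nodes[c])
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].edge.length = float(max(la, 0.0))
    nodes[b].edge.length = float(max(lb, 0.0))
    nodes[c].edge.length = float(max(lc, 0.0))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tip_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal-edge bipartitions keyed by the normalized tip-label side.

    The side not containing the lexicographically smallest tip is used as
    the key, so keys are invariant to the (arbitrary) traversal rooting.
    """
    all_tips = frozenset(tip_labels(tree))
    ref = min(all_tips)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out[side] = node
    return out


def bootstrap_support(
    aln: Alignment, reps: int, seed: int, model: str = "p"
) -> dendropy.Tree:
    """NJ tree with per-bipartition bootstrap frequencies in [0, 1].

    Columns are resampled with replacement ``reps`` times; each replicate's
    NJ tree votes for the bipartitions of the full-data tree. Supports are
    written into internal node labels.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    full = neighbor_joining(pairwise_distance(aln, model))
    target = _bipartitions(full)
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    mat = _matrix(aln)
    for _ in range(reps):
        cols = rng.integers(0, aln.length, aln.length)
        res = Alignment(
            aln.taxa,
            tuple(
                mat[row, cols].tobytes().decode("ascii")
                for row in range(aln.n_taxa)
            ),
        )
        rep_tree = neighbor_joining(pairwise_distance(res, model))
        for key in _bipartitions(rep_tree):
            if key in counts:
                counts[key] += 1
    for key, node in target.items():
        node.label = f"{counts[key] / reps:.6g}"
    return full


def get_support(node: dendropy.Node) -> float | None:
    """Parse a node's label as a support value, if it is numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def root_with_outgroup(
    tree: dendropy.Tree, outgroup: Iterable[str]
) -> dendropy.Tree:
    """Root on the edge separating the outgroup, splitting it in half.

    The outgroup must form one side of some bipartition (a single tip
    always does); otherwise a :class:`RootingError` is raised. Returns a
    new rooted tree; the input is not modified.
    """
    og = frozenset(outgroup)
    tree = tree.clone(depth=1)
    all_tips = frozenset(tip_labels(tree))
    unknown = og - all_tips
    if unknown:
        raise RootingError(f"outgroup taxa not in tree: {sorted(unknown)}")
    if not og or og == all_tips:
        raise RootingError("outgroup must be a proper non-empty subset of taxa")
    target = None
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if side == og or side == all_tips - og:
            target = node
            break
    if target is None:
        raise RootingError(
            f"outgroup {sorted(og)} does not form one side of any bipartition"
        )
    edge = target.edge
    orig = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, update_bipartitions=False)
    root = tree.seed_node
    children = root.child_nodes()
    if len(children) == 2:
        for ch in children:
            ch.edge.length = orig / 2.0
    tree.is_rooted = True
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root halfway along the longest tip-to-tip path (new tree returned).

    Deterministic: the maximal leaf pair and, on ties, the earlier edge
    along the path are chosen by label order. Robust to zero-length
    branches; a tree of total length zero is returned rooted as-is.
    """
    tree = tree.clone(depth=1)

    def blen(node):
        return node.edge.length or 0.0

    # undirected adjacency over the clone
    adj: dict[int, list] = {}
    nodes = list(tree.preorder_node_iter())
    for nd in nodes:
        if nd.parent_node is not None:
            adj.setdefault(id(nd), []).append((nd.parent_node, blen(nd)))
            adj.setdefault(id(nd.parent_node), []).append((nd, blen(nd)))

    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)

    def bfs(start):
        dist = {id(start): 0.0}
        prev = {id(start): None}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, w in adj.get(id(cur), ()):
                if id(nxt) not in dist:
                    dist[id(nxt)] = dist[id(cur)] + w
                    prev[id(nxt)] = cur
                    stack.append(nxt)
        return dist, prev

    best = None  # (distance, label_a, label_b, leaf_a, leaf_b)
    for a in leaves:
        dist, _ = bfs(a)
        for b in leaves:
            if b.taxon.label <= a.taxon.label:
                continue
            key = (-dist[id(b)], a.taxon.label, b.taxon.label)
            if best is None or key < best[0]:
                best = (key, a, b)
    if best is None or -best[0][0] <= 0.0:
        tree.is_rooted = True
        return tree
    _, a, b = best
    diameter = -best[0][0]
    dist, prev = bfs(a)
    path = [b]
    while path[-1] is not a:
        path.append(prev[id(path[-1])])
    path.reverse()  # a ... b

    half = diameter / 2.0
    cum = 0.0
    for p, q in zip(path, path[1:]):
        # edge between p and q; child node carries the edge
        child = q if q.parent_node is p else p
        l = blen(child)
        if cum + l >= half or (p, q) == (path[-2], path[-1]):
            x = min(max(half - cum, 0.0), l)  # distance from p into the edge
            tree.reroot_at_edge(child.edge, update_bipartitions=False)
            kids = tree.seed_node.child_nodes()
            if len(kids) == 2:
                q_side = next((k for k in kids if _contains(k, q)), kids[0])
                p_side = next(k for k in kids if k is not q_side)
                p_side.edge.length = x
                q_side.edge.length = l - x
            tree.is_rooted = True
            return tree
        cum += l
    tree.is_rooted = True  # pragma: no cover - loop always reroots
    return tree


def _contains(ancestor: dendropy.Node, node: dendropy.Node) -> bool:
    cur = node
    while cur is not None:
        if cur is ancestor:
            return True
        cur = cur.parent_node
    return False


def prune_taxa(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Tree:
    """Remove the given tips (new tree returned), suppressing unifurcations."""
    tree = tree.clone(depth=1)
    tree.prune_taxa_with_labels(list(labels))
    return tree


def read_newick(source: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal string.

    ``rooted=None`` respects any [&R]/[&U] token (defaulting to rooted);
    True/False forces the flag.
    """
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    rooting = "default-rooted"
    if rooted is True:
        rooting = "force-rooted"
    elif rooted is False:
        rooting = "force-unrooted"
    tree = dendropy.Tree.get(
        data=text, schema="newick", rooting=rooting,
        suppress_internal_node_taxa=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Write Newick with >=10 significant digits on branch lengths."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=False,
        suppress_internal_node_labels=False,
        real_value_format_specifier=".10g",
    )
    if path is not None:
        Path(path).write_text(s)
    return s
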