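"""Neighbor-joining trees with nonparametric bootstrap and monophyly queries.

The Saitou–Nei agglomeration is run on a complete distance matrix with the
rate-corrected Q criterion

    Q(i,j) = (m - 2) d(i,j) - r_i - r_j,        r_i = sum_k d(i,k)

joining the pair with minimal Q; branch lengths come from the usual
two-point formulas and the reduced matrix from
d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2.  NJ recovers any additive
(four-point) matrix exactly.  Determinism: taxa are sorted lexicographically
before agglomeration and exact Q ties are broken by the smallest (i,j) index
pair; negative branch lengths are clamped to zero with the deficit moved to
the sibling edge (raw lengths kept in a diagnostic field).

Trees are unrooted; bipartitions (the leaf set on one side of each internal
edge) drive both bootstrap support and monophyly tests, so rooting or leaf
order never changes the answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import CANONICAL
from .distances import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    encode_alignment,
    matrix_from_encoded,
)
from .seqio import AlignedMatrix, SequenceRecord


class TreeError(ValueError):
    pass


@dataclass
class Edge:
    a: int
    b: int
    length: float
    raw_length: float
    support: float | None = None


@dataclass
class PhyloTree:
    """Unrooted tree: integer nodes, leaf names, weighted edges."""

    leaf_names: dict[int, str]
    edges: list[Edge]
    skipped_bootstrap_replicates: int = 0

    @property
    def leaves(self) -> set[str]:
        return set(self.leaf_names.values())

    def _adjacency(self) -> dict[int, list[tuple[int, Edge]]]:
        adj: dict[int, list[tuple[int, Edge]]] = {}
        for e in self.edges:
            adj.setdefault(e.a, []).append((e.b, e))
            adj.setdefault(e.b, []).append((e.a, e))
        return adj

    def _side_leaves(self, edge: Edge) -> set[str]:
        """Leaf names reachable from edge.a without crossing the edge."""
        adj = self._adjacency()
        seen = {edge.b}
        stack = [edge.a]
        names = set()
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            if v in self.leaf_names:
                names.add(self.leaf_names[v])
            for w, e in adj.get(v, []):
                if e is edge:
                    continue
                stack.append(w)
        return names

    def bipartitions(self) -> dict[frozenset[str], Edge]:
        """Internal-edge bipartitions, canonicalized.

        Each bipartition is represented by the side *not* containing the
        lexicographically smallest leaf, so it is rooting-invariant.
        """
        anchor = min(self.leaves)
        out: dict[frozenset[str], Edge] = {}
        for e in self.edges:
            side = self._side_leaves(e)
            if anchor in side:
                side = self.leaves - side
            if 2 <= len(side) <= len(self.leaves) - 2:
                out[frozenset(side)] = e
        return out

    def path_length(self, name_a: str, name_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        rev = {v: k for k, v in self.leaf_names.items()}
        start, goal = rev[name_a], rev[name_b]
        adj = self._adjacency()
        stack = [(start, -1, 0.0)]
        while stack:
            v, parent, acc = stack.pop()
            if v == goal:
                return acc
            for w, e in adj.get(v, []):
                if w != parent:
                    stack.append((w, v, acc + e.length))
        raise TreeError("disconnected tree")

    def to_newick(self, root: int | None = None) -> str:
        """Newick string; supports become internal-node labels."""
        adj = self._adjacency()
        if root is None:
            internal = [v for v in adj if v not in self.leaf_names]
            root = internal[0] if internal else next(iter(adj))

        def fmt(v: int, parent: int, edge: Edge | None) -> str:
            children = [
                (w, e) for w, e in adj.get(v, []) if w != parent
            ]
            if v in self.leaf_names and not children:
                body = self.leaf_names[v]
            else:
                inner = ",".join(fmt(w, v, e) for w, e in children)
                label = ""
                if edge is not None and edge.support is not None:
                    label = f"{edge.support:g}"
                body = f"({inner}){label}"
            if edge is not None:
                body += f":{edge.length:.10g}"
            return body

        children = [(w, e) for w, e in adj.get(root, [])]
        inner = ",".join(fmt(w, root, e) for w, e in children)
        return f"({inner});"


def complete_deletion(alignment: AlignedMatrix) -> AlignedMatrix:
    """Drop every column holding a gap or degenerate residue in any sequence."""
    if len(alignment) < 2:
        raise TreeError("need at least 2 records")
    canon = set(CANONICAL)
    keep = [
        col
        for col in range(alignment.n_columns)
        if all(r.residues[col] in canon for r in alignment.records)
    ]
    if not keep:
        raise TreeError("complete deletion removed every column")
    records = [
        SequenceRecord(
            id=r.id,
            residues="".join(r.residues[c] for c in keep),
            species=r.species,
            region_tag=r.region_tag,
        )
        for r in alignment.records
    ]
    return AlignedMatrix(records=records, label_map=dict(alignment.label_map))


def _nj_from_array(D: np.ndarray, names: list[str]) -> PhyloTree:
    """Core NJ on a complete array whose rows follow ``names`` order."""
    m = len(names)
    active = list(range(m))  # node ids of active clusters
    node_count = m
    # distances between active clusters, indexed by position in `active`
    D = D.astype(float).copy()
    edges: list[Edge] = []

    while len(active) > 2:
        k = len(active)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair attaining the exact minimum
        # Q is only symmetric up to float rounding, so canonicalize indices
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        i, j = min(
            (min(int(a), int(b)), max(int(a), int(b))) for a, b in ties
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        # clamp negatives, shifting the deficit to the sibling branch
        raw_li, raw_lj = li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = node_count
        node_count += 1
        edges.append(Edge(a=active[i], b=new, length=li, raw_length=raw_li))
        edges.append(Edge(a=active[j], b=new, length=lj, raw_length=raw_lj))
        # reduced distances
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.empty((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[x] for x in keep] + [new]

    # connect the last two clusters
    length = float(D[0, 1])
    raw = length
    length = max(length, 0.0)
    edges.append(Edge(a=active[0], b=active[1], length=length, raw_length=raw))
    return PhyloTree(leaf_names=dict(enumerate(names)), edges=edges)


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ tree from a complete distance matrix.

    Taxa are sorted lexicographically first so the result is independent of
    input order.  Undefined (NaN) distances are an error: run
    :func:`complete_deletion` (or impute) before building the matrix.
    """
    if len(matrix.ids) < 3:
        raise TreeError("need at least 3 taxa")
    if np.isnan(matrix.values).any():
        raise TreeError(
            "distance matrix has undefined entries; apply complete_deletion "
            "to the alignment (or impute) before tree building"
        )
    order = sorted(range(len(matrix.ids)), key=lambda i: matrix.ids[i])
    names = [matrix.ids[i] for i in order]
    D = matrix.values[np.ix_(order, order)]
    return _nj_from_array(D, names)


def bootstrap_support(
    alignment: AlignedMatrix,
    model: str = "k2p",
    replicates: int = 1000,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PhyloTree:
    """NJ tree with bootstrap supports on its internal edges.

    Columns of the complete-deletion alignment are resampled with
    replacement per replicate; the support of each bipartition of the
    full-data tree is the percentage of successful replicate trees that
    contain it.  Replicates whose matrix has an undefined pair are skipped
    and counted in ``skipped_bootstrap_replicates``.
    """
    clean = complete_deletion(alignment)
    ids = clean.ids
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    names = [ids[i] for i in order]
    X = encode_alignment([clean.records[i].residues for i in order])
    d_full, _ = matrix_from_encoded(X, model=model, min_overlap=min_overlap)
    if np.isnan(d_full).any():
        raise TreeError("undefined distances even after complete deletion")
    tree = _nj_from_array(d_full, names)
    target = tree.bipartitions()
    hits = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    L = X.shape[1]
    skipped = 0
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        d, _ = matrix_from_encoded(X[:, cols], model=model, min_overlap=min_overlap)
        if np.isnan(d).any():
            skipped += 1
            continue
        rep = _nj_from_array(d, names)
        rep_bps = set(rep.bipartitions())
        for bp in hits:
            if bp in rep_bps:
                hits[bp] += 1
        done += 1
    denom = max(done, 1)
    for bp, edge in target.items():
        edge.support = 100.0 * hits[bp] / denom
    tree.skipped_bootstrap_replicates = skipped
    return tree


def is_monophyletic(tree: PhyloTree, ids: set[str]) -> bool:
    """True iff some bipartition separates exactly ``ids`` from the rest."""
    ids = set(ids)
    unknown = ids - tree.leaves
    if unknown:
        raise TreeError(f"unknown leaf ids: {sorted(unknown)}")
    if len(ids) in (1, len(tree.leaves)):
        return True
    anchor = min(tree.leaves)
    canonical = frozenset(ids if anchor not in ids else tree.leaves - ids)
    return canonical in tree.bipartitions()
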