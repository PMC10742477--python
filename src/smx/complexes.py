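"""Simplicial complexes built from graphs, and their discrete Hodge operators.

A geometric simplicial complex is represented combinatorially: for each
dimension ``m`` the ``m``-simplices are strictly increasing ``(m+1)``-tuples of
vertex ids, the collection being closed under taking faces.  Orientation is
induced by the vertex order, so the signed incidence (boundary) matrices
``B_m`` and the higher-order (Hodge) Laplacians

    L_m = B_m^T B_m + B_{m+1} B_{m+1}^T

are uniquely determined by the vertex labelling.  ``L_0`` coincides with the
ordinary graph Laplacian ``K - A`` of the 1-skeleton, and the dimension of the
kernel of ``L_m`` is the Betti number ``beta_m``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "SimplicialComplex",
    "HodgeOperators",
    "read_edge_list",
    "clique_complex",
    "simplex_counts",
    "incidence_matrix",
    "hodge_laplacians",
    "betti_numbers",
]


def _label_sort_key(label):
    """Sort labels numerically when they all look like integers, else as text."""
    s = str(label)
    try:
        return (0, int(s), s)
    except ValueError:
        return (1, 0, s)


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with vertices relabelled to ``0..k``.

    ``labels[i]`` is the original label of vertex ``i``; edges are stored as
    sorted pairs ``(i, j)`` with ``i < j``.
    """

    labels: tuple
    edges: frozenset

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on vertex {self.labels[i]!r}")
            if not (0 <= i < j < len(self.labels)):
                raise ValueError(f"edge {(i, j)} out of range or unsorted")

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def id_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown vertex label {label!r}") from None

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    @classmethod
    def from_label_pairs(cls, pairs: Iterable[tuple]) -> "Graph":
        """Build from an iterable of (label, label) pairs.

        Labels are mapped to ``0..k`` in sorted label order; duplicate and
        reversed pairs are identified.  Self-loops are rejected.
        """
        pairs = list(pairs)
        for row, (a, b) in enumerate(pairs):
            if a == b:
                raise ValueError(f"self-loop {a!r}-{b!r} at row {row}")
        labels = sorted({a for p in pairs for a in p}, key=_label_sort_key)
        idx = {lab: i for i, lab in enumerate(labels)}
        edges = frozenset(
            tuple(sorted((idx[a], idx[b]))) for a, b in pairs
        )
        return cls(labels=tuple(labels), edges=edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g


def read_edge_list(path, format: str | None = None) -> Graph:
    """Read an undirected graph from a two-column TSV edge list or GraphML.

    TSV rows hold at least two whitespace-separated tokens; lines starting
    with ``#`` (and blank lines) are skipped.  ``(a, b)`` and ``(b, a)`` are
    identified and duplicates collapse.  Vertex labels are remapped to
    ``0..k`` in sorted label order (the mapping is retained on the result).
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "tsv"
    if format == "graphml":
        g = nx.read_graphml(path)
        pairs = [(str(a), str(b)) for a, b in g.edges()]
        if not pairs:
            raise ValueError(f"no edges found in {path}")
        return Graph.from_label_pairs(pairs)
    if format != "tsv":
        raise ValueError(f"unknown edge-list format {format!r}")

    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {stripped!r}")
            a, b = tokens[0], tokens[1]
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop {a!r}")
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"empty edge list: {path}")
    return Graph.from_label_pairs(pairs)


class SimplicialComplex:
    """A face-closed collection of simplices with canonical column order.

    Simplices of dimension ``m`` are strictly increasing ``(m+1)``-tuples of
    vertex ids; within each dimension they are sorted lexicographically, which
    fixes the columns of every operator matrix.  The global (block) ordering
    used for the total Laplacian and for metaplex assembly is dimension-major.
    """

    def __init__(
        self,
        simplices: Mapping[int, Iterable[Sequence[int]]],
        vertex_labels: Sequence | None = None,
        validate: bool = True,
    ):
        self.simplices: dict[int, list[tuple]] = {}
        max_dim = -1
        for m, items in simplices.items():
            items = sorted(tuple(int(v) for v in s) for s in items)
            if items:
                max_dim = max(max_dim, int(m))
            self.simplices[int(m)] = items
        if max_dim < 0:
            raise ValueError("empty simplicial complex")
        self.max_dim = max_dim
        for m in range(max_dim + 1):
            self.simplices.setdefault(m, [])
        if vertex_labels is None:
            vertex_labels = [s[0] for s in self.simplices[0]]
        self.vertex_labels = tuple(vertex_labels)

        self.index: dict[int, dict[tuple, int]] = {
            m: {s: k for k, s in enumerate(self.simplices[m])}
            for m in range(max_dim + 1)
        }
        if validate:
            self._validate()

    def _validate(self) -> None:
        for m, items in self.simplices.items():
            for s in items:
                if len(s) != m + 1:
                    raise ValueError(f"{s} is not a {m}-simplex")
                if any(a >= b for a, b in zip(s, s[1:])):
                    raise ValueError(f"simplex {s} is not strictly increasing")
                if len(set(s)) != len(s):
                    raise ValueError(f"repeated vertex in simplex {s}")
            if len(set(items)) != len(items):
                raise ValueError(f"duplicate {m}-simplices")
        # closure under faces
        for m in range(1, self.max_dim + 1):
            faces = self.index[m - 1]
            for s in self.simplices[m]:
                for p in range(m + 1):
                    face = s[:p] + s[p + 1:]
                    if face not in faces:
                        raise ValueError(f"face {face} of {s} missing: not face-closed")

    # -- bookkeeping -------------------------------------------------------

    def n_simplices(self, m: int) -> int:
        return len(self.simplices.get(m, []))

    @property
    def total_simplices(self) -> int:
        return sum(len(v) for v in self.simplices.values())

    def block_offset(self, m: int) -> int:
        """Start of dimension ``m`` in the dimension-major global ordering."""
        return sum(self.n_simplices(d) for d in range(m))

    def global_index(self, m: int, simplex: Sequence[int]) -> int:
        return self.block_offset(m) + self.index[m][tuple(simplex)]

    def iter_simplices(self) -> Iterator[tuple[int, tuple]]:
        """All simplices in global (dimension-major, lexicographic) order."""
        for m in range(self.max_dim + 1):
            for s in self.simplices[m]:
                yield m, s

    def find_by_labels(self, labels: Sequence) -> tuple[int, tuple]:
        """Map a tuple of original vertex labels to a stored ``(dim, simplex)``."""
        ids = tuple(sorted(self.vertex_labels.index(l) for l in labels))
        m = len(ids) - 1
        if ids not in self.index.get(m, {}):
            raise KeyError(f"simplex with labels {tuple(labels)} not in complex")
        return m, ids

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "vertices": list(self.vertex_labels),
            "simplices": {
                str(m): [list(s) for s in self.simplices[m]]
                for m in range(self.max_dim + 1)
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimplicialComplex":
        payload = json.loads(text)
        simplices = {int(m): [tuple(s) for s in items]
                     for m, items in payload["simplices"].items()}
        return cls(simplices, vertex_labels=payload["vertices"])

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SimplicialComplex":
        return cls.from_json(Path(path).read_text())

    def __repr__(self) -> str:
        counts = ", ".join(f"{m}:{self.n_simplices(m)}" for m in range(self.max_dim + 1))
        return f"SimplicialComplex({{{counts}}})"


def clique_complex(g: Graph, max_dim: int = 2) -> SimplicialComplex:
    """Flag (clique) complex of a graph up to ``max_dim`` (at most 3).

    Every ``(m+1)``-clique of the graph becomes an ``m``-simplex, so the
    result is face-closed by construction.  In particular every triangle of
    the graph is filled with a 2-simplex.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    if max_dim > 3:
        raise ValueError("max_dim is capped at 3 (tetrahedra)")
    nbrs: dict[int, set[int]] = {v: set() for v in range(g.n_vertices)}
    for i, j in g.edges:
        nbrs[i].add(j)
        nbrs[j].add(i)

    simplices: dict[int, list] = {0: [(v,) for v in range(g.n_vertices)]}
    if max_dim >= 1:
        simplices[1] = sorted(g.edges)
    if max_dim >= 2:
        triangles = []
        for i, j in sorted(g.edges):
            for k in sorted(nbrs[i] & nbrs[j]):
                if k > j:
                    triangles.append((i, j, k))
        simplices[2] = triangles
    if max_dim >= 3:
        tets = []
        for i, j, k in simplices[2]:
            for l in sorted(nbrs[i] & nbrs[j] & nbrs[k]):
                if l > k:
                    tets.append((i, j, k, l))
        simplices[3] = tets
    return SimplicialComplex(simplices, vertex_labels=g.labels, validate=False)


def simplex_counts(K: SimplicialComplex) -> dict[int, int]:
    """Number of simplices per dimension (dimensions with none are omitted)."""
    return {m: K.n_simplices(m) for m in range(K.max_dim + 1) if K.n_simplices(m)}


def incidence_matrix(K: SimplicialComplex, m: int) -> sp.csr_matrix:
    """Signed boundary matrix ``B_m`` mapping ``m``-simplices to their faces.

    Shape is (#(m-1)-simplices, #m-simplices).  With simplices stored as
    strictly increasing tuples, the face obtained by deleting the vertex at
    position ``p`` carries sign ``(-1)^p`` — the sign of the permutation that
    orders the face vertices together with the deleted one.  For an edge
    ``[i, j]`` this gives the gradient convention ``-1`` at row ``i`` and
    ``+1`` at row ``j``.
    """
    if not (1 <= m <= K.max_dim):
        raise ValueError(f"m={m} out of range 1..{K.max_dim}")
    rows, cols, data = [], [], []
    face_index = K.index[m - 1]
    for col, s in enumerate(K.simplices[m]):
        for p in range(m + 1):
            face = s[:p] + s[p + 1:]
            rows.append(face_index[face])
            cols.append(col)
            data.append(1.0 if p % 2 == 0 else -1.0)
    return sp.csr_matrix(
        (data, (rows, cols)),
        shape=(K.n_simplices(m - 1), K.n_simplices(m)),
    )


@dataclass
class HodgeOperators:
    """All discrete operators of a complex: boundaries, Laplacians, 1-skeleton.

    ``L_total`` is block-diagonal over dimensions (dimension-major order,
    lexicographic within each dimension), matching
    :meth:`SimplicialComplex.iter_simplices`.
    """

    complex: SimplicialComplex
    B: dict[int, sp.csr_matrix]
    L: dict[int, sp.csr_matrix]
    L_total: sp.csr_matrix
    degree: sp.csr_matrix
    adjacency: sp.csr_matrix

    def block_slice(self, m: int) -> slice:
        off = self.complex.block_offset(m)
        return slice(off, off + self.complex.n_simplices(m))


def hodge_laplacians(K: SimplicialComplex) -> HodgeOperators:
    """Assemble ``B_m``, ``L_m = B_m^T B_m + B_{m+1} B_{m+1}^T`` and the
    block-diagonal total Laplacian, with ``B_0`` and ``B_{M+1}`` empty."""
    M = K.max_dim
    B = {m: incidence_matrix(K, m) for m in range(1, M + 1)}
    L: dict[int, sp.csr_matrix] = {}
    for m in range(M + 1):
        n_m = K.n_simplices(m)
        down = B[m].T @ B[m] if m >= 1 else sp.csr_matrix((n_m, n_m))
        up = B[m + 1] @ B[m + 1].T if m + 1 in B else sp.csr_matrix((n_m, n_m))
        L[m] = (down + up).tocsr()
    L_total = sp.block_diag([L[m] for m in range(M + 1)], format="csr")

    n0 = K.n_simplices(0)
    rows, cols = [], []
    for i, j in sorted(K.simplices.get(1, [])):
        rows += [i, j]
        cols += [j, i]
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n0, n0))
    Kdeg = sp.diags(np.asarray(A.sum(axis=1)).ravel(), format="csr")
    return HodgeOperators(complex=K, B=B, L=L, L_total=L_total, degree=Kdeg, adjacency=A)


def _rank(mat: sp.spmatrix | None, tol_factor: float) -> int:
    if mat is None or min(mat.shape) == 0:
        return 0
    svals = np.linalg.svd(mat.toarray(), compute_uv=False)
    if svals.size == 0:
        return 0
    return int(np.sum(svals > tol_factor * svals[0]))


def betti_numbers(K: SimplicialComplex, tol: float = 1e-8) -> list[int]:
    """Betti numbers ``beta_0..beta_M`` via numerical ranks of the boundaries.

    ``beta_m = n_m - rank(B_m) - rank(B_{m+1})``, the kernel dimension of the
    ``m``-th Hodge Laplacian; ``beta_0`` is the number of connected
    components.  Ranks use an SVD cutoff of ``tol`` times the largest
    singular value.
    """
    M = K.max_dim
    B = {m: incidence_matrix(K, m) for m in range(1, M + 1)}
    betti = []
    for m in range(M + 1):
        r_down = _rank(B.get(m), tol)
        r_up = _rank(B.get(m + 1), tol)
        betti.append(K.n_simplices(m) - r_down - r_up)
    return betti
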