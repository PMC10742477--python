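"""P1 finite-element discretization of reference simplices.

Each simplex of the complex becomes a continuous domain: a point (dim 0), the
unit segment (dim 1), or the unit equilateral triangle (dim 2).  Domains carry
a piecewise-linear stiffness matrix (the discrete Laplacian with natural
Neumann boundaries, so row sums vanish) and a lumped diagonal mass normalized
so every simplex has measure 1 — without the rescaling a triangle would weigh
sqrt(3)/4 and the diffusive steady state would no longer be a single shared
density.  Coordinates are local to the reference simplex; no global embedding
is kept.

The structured triangulation uses ``n`` nodes per side, hence ``n(n+1)/2``
nodes in total (210 for the n=20 resolution).  Boundary node lists per face
are ordered from the lower- to the higher-labelled corner so that matched
couplings between a triangle side and the corresponding segment domain line up
index by index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

__all__ = ["Domain", "NotSupportedError", "discretize_simplex"]


class NotSupportedError(NotImplementedError):
    """Requested discretization is outside the supported dimensions."""


@dataclass
class Domain:
    """A discretized simplex: nodes, stiffness, unit lumped mass, face nodes.

    ``face_nodes`` maps a local face key — a local corner index for segment
    endpoints, a pair of local corner indices for triangle sides — to the
    ordered list of boundary node indices on that face.
    """

    dim: int
    coords: np.ndarray          # (n_nodes, dim) reference coordinates
    stiffness: sp.csr_matrix    # symmetric, zero row sums, Metzler off-diagonal
    mass: np.ndarray            # positive, sums to 1
    face_nodes: dict
    simplex: tuple | None = None  # global vertex tuple once instantiated

    @property
    def n_nodes(self) -> int:
        return len(self.mass)

    def interior_nodes(self) -> np.ndarray:
        boundary = set()
        for nodes in self.face_nodes.values():
            boundary.update(nodes)
        return np.array([a for a in range(self.n_nodes) if a not in boundary], dtype=int)

    def with_simplex(self, simplex: tuple) -> "Domain":
        return replace(self, simplex=tuple(simplex))


def _segment_domain(n: int) -> Domain:
    h = 1.0 / (n - 1)
    coords = np.linspace(0.0, 1.0, n)[:, None]
    main = np.full(n, 2.0 / h)
    main[0] = main[-1] = 1.0 / h
    off = np.full(n - 1, -1.0 / h)
    stiffness = sp.diags([off, main, off], offsets=[-1, 0, 1], format="csr")
    mass = np.full(n, h)
    mass[0] = mass[-1] = h / 2.0
    return Domain(
        dim=1,
        coords=coords,
        stiffness=stiffness,
        mass=mass,
        face_nodes={0: [0], 1: [n - 1]},
    )


def _triangle_domain(n: int) -> Domain:
    h = 1.0 / (n - 1)
    e1 = np.array([1.0, 0.0])
    e2 = np.array([0.5, np.sqrt(3.0) / 2.0])

    node_id: dict[tuple[int, int], int] = {}
    coords = []
    for r in range(n):            # rows towards corner 2
        for c in range(n - r):    # columns towards corner 1
            node_id[(r, c)] = len(coords)
            coords.append(c * h * e1 + r * h * e2)
    coords = np.array(coords)

    elements = []
    for r in range(n - 1):
        for c in range(n - 1 - r):
            elements.append((node_id[(r, c)], node_id[(r, c + 1)], node_id[(r + 1, c)]))
            if c < n - 2 - r:
                elements.append(
                    (node_id[(r, c + 1)], node_id[(r + 1, c + 1)], node_id[(r + 1, c)])
                )

    rows, cols, data = [], [], []
    mass = np.zeros(len(coords))
    for tri in elements:
        p = coords[list(tri)]
        b = np.array([p[1, 1] - p[2, 1], p[2, 1] - p[0, 1], p[0, 1] - p[1, 1]])
        c_ = np.array([p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]])
        area = 0.5 * abs(b[0] * c_[1] - b[1] * c_[0])
        Ke = (np.outer(b, b) + np.outer(c_, c_)) / (4.0 * area)
        for a in range(3):
            mass[tri[a]] += area / 3.0
            for bb in range(3):
                rows.append(tri[a])
                cols.append(tri[bb])
                data.append(Ke[a, bb])
    stiffness = sp.csr_matrix((data, (rows, cols)), shape=(len(coords),) * 2)
    stiffness.sum_duplicates()
    mass /= mass.sum()  # unit measure; raw total is the area sqrt(3)/4

    side_01 = [node_id[(0, c)] for c in range(n)]
    side_02 = [node_id[(r, 0)] for r in range(n)]
    side_12 = [node_id[(r, n - 1 - r)] for r in range(n)]
    return Domain(
        dim=2,
        coords=coords,
        stiffness=stiffness,
        mass=mass,
        face_nodes={(0, 1): side_01, (0, 2): side_02, (1, 2): side_12},
    )


def discretize_simplex(dim: int, nodes_per_edge: int = 20) -> Domain:
    """Build the reference domain of a ``dim``-simplex.

    dim 0 is a single node of mass 1 with zero stiffness; dim 1 a path of
    ``nodes_per_edge`` nodes on the unit segment; dim 2 a structured mesh of
    the unit equilateral triangle with ``nodes_per_edge`` nodes per side.
    Tetrahedral domains are not meshed (raises :class:`NotSupportedError`).
    """
    if dim == 0:
        return Domain(
            dim=0,
            coords=np.zeros((1, 1)),
            stiffness=sp.csr_matrix((1, 1)),
            mass=np.ones(1),
            face_nodes={},
        )
    if nodes_per_edge < 2:
        raise ValueError("nodes_per_edge must be >= 2")
    if dim == 1:
        return _segment_domain(nodes_per_edge)
    if dim == 2:
        return _triangle_domain(nodes_per_edge)
    raise NotSupportedError(f"no domain discretization for {dim}-simplices")
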