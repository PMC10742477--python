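"""Assembly of simplicial metaplexes: discretized simplices wired by sinks and
sources across dimension-adjacent faces.

A metaplex couples continuous domains through matched boundary regions.  For a
geometric simplicial complex the rule is: each triangle side is matched
one-to-one (node by node) with the full segment domain of the corresponding
1-simplex, and each segment endpoint with the single node of its 0-simplex —
so exchange happens only between simplices whose dimensions differ by one,
mirroring the incidence structure that underlies the Hodge Laplacians.

The semi-discrete dynamics are ``D du/dt = -S u`` with ``D`` the concatenated
lumped masses and ``S = blockdiag(stiffness) + C``, where every matched node
pair (a, b) of conductance kappa contributes a two-node graph-Laplacian
stencil to the coupling matrix ``C``.  ``S`` is symmetric with zero column
sums, so the flow conserves total mass ``sum(D u)`` exactly; its off-diagonal
entries are non-positive (−S is Metzler), which is what preserves positivity
under implicit time stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .complexes import SimplicialComplex
from .domains import Domain, NotSupportedError, discretize_simplex

__all__ = [
    "SinkSource",
    "MetaplexSystem",
    "build_metaplex",
    "transition_matrix",
    "assemble_generator",
]


@dataclass
class SinkSource:
    """Bidirectional boundary coupling between two domains.

    ``pairs`` are one-to-one matched local node indices (a in domain i,
    b in domain j); each pair exchanges flux kappa * (u_a - u_b).
    """

    i: int
    j: int
    pairs: list
    conductance: float = 1.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a sink-source must join two distinct domains")
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("matched pairs must be one-to-one")

    @property
    def total_conductance(self) -> float:
        return self.conductance * len(self.pairs)

    def reversed(self) -> "SinkSource":
        return SinkSource(self.j, self.i, [(b, a) for a, b in self.pairs],
                          self.conductance)


class MetaplexSystem:
    """Domains plus couplings with the assembled mass/flow pair (D, S).

    Domains are ordered like the blocks of the total Hodge Laplacian
    (dimension-major, lexicographic), so per-simplex aggregates of the two
    models line up index by index.
    """

    def __init__(self, domains: list[Domain], couplings: list[SinkSource],
                 complex: SimplicialComplex | None = None,
                 nodes_per_edge: int | None = None):
        self.domains = list(domains)
        self.couplings = list(couplings)
        self.complex = complex
        self.nodes_per_edge = nodes_per_edge

        self.offsets = np.zeros(len(domains) + 1, dtype=int)
        for k, dom in enumerate(self.domains):
            self.offsets[k + 1] = self.offsets[k] + dom.n_nodes
        self.D = np.concatenate([dom.mass for dom in self.domains])
        self._index = {(dom.dim, dom.simplex): k
                       for k, dom in enumerate(self.domains) if dom.simplex is not None}
        self.S = self._assemble_flow()

    # -- structure ---------------------------------------------------------

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_dofs(self) -> int:
        return int(self.offsets[-1])

    @property
    def total_measure(self) -> float:
        return float(self.D.sum())

    def dof_slice(self, k: int) -> slice:
        return slice(self.offsets[k], self.offsets[k + 1])

    def domain_index(self, simplex) -> int:
        """Look up a domain by (dim, vertex-tuple) or by vertex-tuple alone."""
        if (isinstance(simplex, tuple) and len(simplex) == 2
                and isinstance(simplex[1], tuple)):
            key = (int(simplex[0]), tuple(simplex[1]))
        else:
            t = tuple(simplex)
            key = (len(t) - 1, t)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no domain for simplex {simplex!r}") from None

    def _assemble_flow(self) -> sp.csr_matrix:
        blocks = sp.block_diag([dom.stiffness for dom in self.domains], format="lil")
        S = blocks.tocsr().tolil()
        for c in self.couplings:
            oi, oj = self.offsets[c.i], self.offsets[c.j]
            k = c.conductance
            for a, b in c.pairs:
                ga, gb = oi + a, oj + b
                S[ga, ga] += k
                S[gb, gb] += k
                S[ga, gb] -= k
                S[gb, ga] -= k
        return S.tocsr()


def build_metaplex(K: SimplicialComplex, nodes_per_edge: int = 20,
                   kappa: float = 1.0, kappa_mode: str = "per_pair") -> MetaplexSystem:
    """Discretize every simplex of a face-closed complex and wire the couplings.

    Each (face, coface) incidence becomes one bidirectional sink-source:
    triangle sides pair node-by-node with the full segment of the shared
    1-simplex (both ordered from the lower- to the higher-labelled vertex, so
    shared corners line up), and segment endpoints pair with their vertices.
    ``kappa_mode='per_pair'`` gives every matched pair conductance ``kappa``
    (pairs act as unit-weight graph edges); ``'normalized'`` divides ``kappa``
    across the pairs of each coupling so the domain-level total is
    resolution-independent.
    """
    if kappa_mode not in ("per_pair", "normalized"):
        raise ValueError(f"unknown kappa_mode {kappa_mode!r}")
    if K.max_dim >= 3 and K.n_simplices(3):
        raise NotSupportedError("metaplex discretization of 3-simplices is not supported")

    reference = {m: discretize_simplex(m, nodes_per_edge)
                 for m in range(min(K.max_dim, 2) + 1)}
    domains = [reference[m].with_simplex(s) for m, s in K.iter_simplices()]
    index = {(m, s): k for k, (m, s) in enumerate(K.iter_simplices())}

    n = nodes_per_edge
    couplings = []
    for m in range(1, K.max_dim + 1):
        for s in K.simplices[m]:
            i = index[(m, s)]
            for p in range(m + 1):
                face = s[:p] + s[p + 1:]
                j = index[(m - 1, face)]
                if m == 1:
                    # the surviving vertex of the edge meets the 0-domain node
                    local = 0 if s[0] == face[0] else 1
                    end_node = domains[i].face_nodes[local][0]
                    pairs = [(end_node, 0)]
                else:  # m == 2: side between the two surviving local corners
                    side_key = tuple(q for q in range(3) if q != p)
                    side = domains[i].face_nodes[side_key]
                    pairs = list(zip(side, range(n)))
                k_pair = kappa if kappa_mode == "per_pair" else kappa / len(pairs)
                couplings.append(SinkSource(i, j, pairs, k_pair))
    return MetaplexSystem(domains, couplings, complex=K, nodes_per_edge=nodes_per_edge)


def transition_matrix(M: MetaplexSystem) -> np.ndarray:
    """Domain-level summary of the couplings.

    Off-diagonal (i, j) is the total conductance exchanged between domains j
    and i; diagonals are minus the total conductance leaving each domain, so
    columns sum to zero.  Distinct metaplexes (e.g. different sink/source
    placements) can share this matrix yet behave differently.
    """
    T = np.zeros((M.n_domains, M.n_domains))
    for c in M.couplings:
        g = c.total_conductance
        T[c.i, c.j] += g
        T[c.j, c.i] += g
        T[c.i, c.i] -= g
        T[c.j, c.j] -= g
    return T


def assemble_generator(M: MetaplexSystem) -> tuple[np.ndarray, sp.csr_matrix]:
    """Mass vector D and flow matrix S of the dynamics D du/dt = -S u."""
    return M.D, M.S
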