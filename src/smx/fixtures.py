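"""Deterministic fixture generators.

Everything the pipeline needs can be generated in memory: the five-node
two-triangle complex used throughout as the worked example, complete graphs,
seeded Erdős–Rényi clique complexes standing in for connectome-scale input
(the real macaque visual-cortex network — 30 areas, 190 connections — is a
user-supplied download, never bundled), and the two-segment metaplex whose
variants share a transition matrix but not their transients.
"""

from __future__ import annotations

import networkx as nx

from .complexes import Graph, SimplicialComplex, clique_complex
from .domains import discretize_simplex
from .metaplex import MetaplexSystem, SinkSource

__all__ = [
    "two_triangle_complex",
    "k3_complex",
    "random_clique_complex",
    "synthetic_connectome",
    "two_domain_metaplex",
]


def two_triangle_complex() -> SimplicialComplex:
    """Five vertices, six edges, two filled triangles sharing vertex 3.

    Vertices are labelled 1..5 (internally 0..4); triangles (1,2,3) and
    (3,4,5) are filled, so both cycles are capped and the Betti numbers are
    (1, 0, 0).  This is the minimal face-closed complex on which the
    total-Laplacian pathologies (negativity, lost mass, split consensus) are
    demonstrated.
    """
    g = Graph.from_label_pairs(
        [(1, 2), (1, 3), (2, 3), (3, 4), (3, 5), (4, 5)]
    )
    return clique_complex(g, max_dim=2)


def k3_complex() -> SimplicialComplex:
    """The filled triangle on three vertices."""
    g = Graph.from_label_pairs([(0, 1), (0, 2), (1, 2)])
    return clique_complex(g, max_dim=2)


def random_clique_complex(n_vertices: int, p_edge: float, seed: int,
                          max_dim: int = 2) -> SimplicialComplex:
    """Clique complex of a seeded Erdős–Rényi graph (reproducible per seed)."""
    if not (0 <= p_edge <= 1):
        raise ValueError("p_edge must lie in [0, 1]")
    g_nx = nx.gnp_random_graph(n_vertices, p_edge, seed=seed)
    pairs = list(g_nx.edges())
    if pairs:
        g = Graph(labels=tuple(range(n_vertices)),
                  edges=frozenset(tuple(sorted(e)) for e in pairs))
    else:
        g = Graph(labels=tuple(range(n_vertices)), edges=frozenset())
    return clique_complex(g, max_dim=max_dim)


def synthetic_connectome(seed: int = 0) -> SimplicialComplex:
    """Synthetic 30-node stand-in for a cortical connectome.

    Edge probability 190/435 matches the density of the macaque visual-cortex
    network (30 areas, 190 connections); the triangles are filled as in the
    connectome pipeline.  This is a synthetic surrogate for exercising the
    pipeline, not the anatomical network itself.
    """
    return random_clique_complex(30, 190 / 435, seed=seed, max_dim=2)


def two_domain_metaplex(separated: bool = False, nodes_per_edge: int = 20,
                        kappa: float = 1.0) -> MetaplexSystem:
    """Two unit segments joined by a single sink-source of total conductance 1.

    ``separated=False``: the exchange happens at one coincident point — the
    right end of the first segment meets the left end of the second.
    ``separated=True``: each segment exchanges at both of its endpoints with
    the opposite ends of the other, through two half-conductance pairs.  Both
    variants reduce to the same domain-level transition matrix
    ``[[-1, 1], [1, -1]]`` yet their transients differ.
    """
    n = nodes_per_edge
    dom_a = discretize_simplex(1, n).with_simplex((0, 1))
    dom_b = discretize_simplex(1, n).with_simplex((2, 3))
    if separated:
        couplings = [
            SinkSource(0, 1, [(n - 1, 0)], kappa / 2.0),
            SinkSource(0, 1, [(0, n - 1)], kappa / 2.0),
        ]
    else:
        couplings = [SinkSource(0, 1, [(n - 1, 0)], kappa)]
    return MetaplexSystem([dom_a, dom_b], couplings)
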