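"""Diffusion driven by graph and higher-order (Hodge) Laplacians.

The linear dynamics x'(t) = -gamma L x(t) are solved spectrally:

    x(t) = sum_j exp(-t gamma mu_j) (psi_j^T x0) psi_j,

where (mu_j, psi_j) is the eigensystem of the symmetric PSD operator L.  On a
connected graph this relaxes to the average of the initial state (consensus).
Run with the block-diagonal total Laplacian of a simplicial complex instead,
the same equation exhibits well-documented pathologies: blocks whose Betti
number vanishes decay to zero, the total "mass" is not conserved, positive
initial data can turn negative, and no global consensus is reached.
:func:`hodge_diagnostics` measures exactly these features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .complexes import HodgeOperators, SimplicialComplex

__all__ = [
    "SpectralData",
    "BlockTrajectory",
    "HodgeReport",
    "spectral_data",
    "spectral_solution",
    "simulate_hodge",
    "deflated_operator",
    "hodge_diagnostics",
    "block_state",
]

_ZERO_TOL = 1e-10


def _as_dense_symmetric(L) -> np.ndarray:
    A = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("operator must be square")
    scale = max(1.0, np.abs(A).max())
    if np.abs(A - A.T).max() > 1e-10 * scale:
        raise ValueError("operator must be symmetric")
    return A


@dataclass
class SpectralData:
    """Eigendecomposition of a symmetric PSD operator.

    ``lambda1``/``v1`` are the first eigenvalue above the zero threshold and
    its eigenvector (the algebraic connectivity pair for a graph Laplacian).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lambda1: float | None
    v1: np.ndarray | None

    @property
    def null_multiplicity(self) -> int:
        cut = _ZERO_TOL * max(1.0, abs(self.eigenvalues[-1]))
        return int(np.sum(self.eigenvalues < cut))


def spectral_data(L) -> SpectralData:
    A = _as_dense_symmetric(L)
    mu, psi = np.linalg.eigh(A)
    cut = _ZERO_TOL * max(1.0, abs(mu[-1]))
    nonzero = np.where(mu > cut)[0]
    if nonzero.size:
        j = nonzero[0]
        return SpectralData(mu, psi, float(mu[j]), psi[:, j].copy())
    return SpectralData(mu, psi, None, None)


def spectral_solution(L, x0, times, gamma: float = 1.0) -> np.ndarray:
    """Solve x' = -gamma L x by eigendecomposition; columns are states per time."""
    A = _as_dense_symmetric(L)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (A.shape[0],):
        raise ValueError(f"x0 has length {x0.size}, operator is {A.shape[0]}x{A.shape[0]}")
    times = np.asarray(times, dtype=float)
    mu, psi = np.linalg.eigh(A)
    coeff = psi.T @ x0
    # (n_modes, n_times) decay factors; eigenvalues clipped at 0 to avoid
    # amplifying -1e-16 round-off into growth at large t
    decay = np.exp(-np.clip(mu, 0.0, None)[:, None] * (gamma * times[None, :]))
    return psi @ (decay * coeff[:, None])


@dataclass
class BlockTrajectory:
    """Trajectory of the total-Laplacian dynamics in dimension-major order."""

    complex: SimplicialComplex
    times: np.ndarray
    states: np.ndarray  # (n_simplices, n_times)

    def block(self, m: int) -> np.ndarray:
        off = self.complex.block_offset(m)
        return self.states[off:off + self.complex.n_simplices(m)]


def block_state(K: SimplicialComplex, assignments: dict) -> np.ndarray:
    """Vector over all simplices (block order) from {(dim, simplex): value}."""
    x = np.zeros(K.total_simplices)
    for (m, s), value in assignments.items():
        x[K.global_index(m, tuple(s))] = value
    return x


def simulate_hodge(H: HodgeOperators, x0, times, gamma: float = 1.0) -> BlockTrajectory:
    """Run x' = -gamma L_total x on the whole complex at once."""
    x0 = np.asarray(x0, dtype=float)
    n = H.complex.total_simplices
    if x0.shape != (n,):
        raise ValueError(f"x0 has length {x0.size}, complex has {n} simplices")
    states = spectral_solution(H.L_total, x0, times, gamma=gamma)
    return BlockTrajectory(H.complex, np.asarray(times, dtype=float), states)


def deflated_operator(L) -> np.ndarray:
    """Remove the slowest non-trivial mode: returns L - lambda1 v1 v1^T.

    This is the patched diffusion operator sometimes used to force a
    non-trivial steady state when the kernel of L is empty on some block;
    ``v1`` joins the kernel of the result.
    """
    sd = spectral_data(L)
    if sd.lambda1 is None:
        raise ValueError("operator has an all-zero spectrum; nothing to deflate")
    A = _as_dense_symmetric(L)
    return A - sd.lambda1 * np.outer(sd.v1, sd.v1)


@dataclass
class HodgeReport:
    """Diagnostics of a total-Laplacian run: where it loses physical meaning."""

    global_min: float
    argmin: tuple  # ((dim, simplex), time)
    total_mass: np.ndarray  # sum of all components per time
    steady_by_dim: dict[int, np.ndarray] = field(default_factory=dict)
    reaches_global_consensus: bool = False


def hodge_diagnostics(traj: BlockTrajectory, H: HodgeOperators,
                      consensus_tol: float = 1e-6) -> HodgeReport:
    K = traj.complex
    flat = int(np.argmin(traj.states))
    row, col = np.unravel_index(flat, traj.states.shape)
    dim_sim = list(K.iter_simplices())[row]

    steady = {}
    for m in range(K.max_dim + 1):
        sd = spectral_data(H.L[m])
        kern = sd.eigenvectors[:, :sd.null_multiplicity]
        x0m = traj.states[K.block_offset(m):K.block_offset(m) + K.n_simplices(m), 0]
        steady[m] = kern @ (kern.T @ x0m)

    limits = np.concatenate([steady[m] for m in sorted(steady)])
    consensus = bool(limits.size and (limits.max() - limits.min()) < consensus_tol)
    return HodgeReport(
        global_min=float(traj.states.min()),
        argmin=(dim_sim, float(traj.times[col])),
        total_mass=traj.states.sum(axis=0),
        steady_by_dim=steady,
        reaches_global_consensus=consensus,
    )
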