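"""Serialization: complex JSON, MatrixMarket export, trajectory CSV/HDF5,
metaplex HDF5, YAML configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .complexes import SimplicialComplex
from .dynamics import Trajectory, simplex_label
from .metaplex import MetaplexSystem, build_metaplex

__all__ = [
    "save_complex",
    "load_complex",
    "write_matrix_market",
    "totals_to_csv",
    "save_trajectory",
    "load_trajectory",
    "save_metaplex",
    "load_metaplex",
    "load_config",
]


def save_complex(K: SimplicialComplex, path) -> None:
    K.save(path)


def load_complex(path) -> SimplicialComplex:
    return SimplicialComplex.load(path)


def write_matrix_market(matrix, path) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(matrix))


def totals_to_csv(traj: Trajectory, path) -> None:
    """Per-simplex mass totals: rows labelled "dim:v0-v1-...", columns times."""
    index = [simplex_label(dim, s) for dim, s in traj.simplex_ids]
    frame = pd.DataFrame(traj.totals, index=index,
                         columns=[f"{t:.10g}" for t in traj.times])
    frame.to_csv(path, index_label="simplex")


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("states", data=traj.states, compression="gzip")
        fh.create_dataset("totals", data=traj.totals, compression="gzip")
        fh.create_dataset("mass_per_step", data=traj.mass_per_step)
        labels = [simplex_label(dim, s) for dim, s in traj.simplex_ids]
        fh.create_dataset("simplex_ids", data=np.array(labels, dtype="S"))
        fh.attrs["global_min"] = traj.global_min
        fh.attrs["converged"] = traj.converged


def load_trajectory(path) -> Trajectory:
    from .dynamics import parse_simplex_label

    with h5py.File(path, "r") as fh:
        labels = [s.decode() for s in fh["simplex_ids"][()]]
        return Trajectory(
            times=fh["times"][()],
            states=fh["states"][()],
            totals=fh["totals"][()],
            simplex_ids=[parse_simplex_label(l) for l in labels],
            mass_per_step=fh["mass_per_step"][()],
            global_min=float(fh.attrs["global_min"]),
            converged=bool(fh.attrs["converged"]),
        )


def save_metaplex(M: MetaplexSystem, path) -> None:
    """Store D, S (triplets), the domain table and offsets; when the system
    was built from a complex the complex and build parameters ride along so
    the full Domain geometry can be reconstructed on load."""
    S = sp.coo_matrix(M.S)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("D", data=M.D)
        grp = fh.create_group("S")
        grp.create_dataset("row", data=S.row)
        grp.create_dataset("col", data=S.col)
        grp.create_dataset("data", data=S.data)
        grp.attrs["shape"] = S.shape
        fh.create_dataset("offsets", data=M.offsets)
        table = [simplex_label(d.dim, d.simplex or ()) for d in M.domains]
        fh.create_dataset("domains", data=np.array(table, dtype="S"))
        if M.complex is not None and M.nodes_per_edge is not None:
            fh.attrs["complex_json"] = M.complex.to_json()
            fh.attrs["nodes_per_edge"] = M.nodes_per_edge
            kappas = {c.conductance for c in M.couplings}
            if len(kappas) == 1:
                fh.attrs["kappa"] = kappas.pop()


def load_metaplex(path) -> MetaplexSystem:
    with h5py.File(path, "r") as fh:
        if "complex_json" not in fh.attrs:
            raise ValueError(
                f"{path} lacks build provenance; rebuild it with build_metaplex")
        K = SimplicialComplex.from_json(fh.attrs["complex_json"])
        M = build_metaplex(
            K,
            nodes_per_edge=int(fh.attrs["nodes_per_edge"]),
            kappa=float(fh.attrs.get("kappa", 1.0)),
        )
        stored = sp.coo_matrix(
            (fh["S/data"][()], (fh["S/row"][()], fh["S/col"][()])),
            shape=tuple(fh["S"].attrs["shape"]),
        ).tocsr()
    diff = (M.S - stored).tocoo()
    if diff.nnz and np.abs(diff.data).max() > 1e-9:
        raise ValueError(f"{path}: stored flow matrix does not match its provenance")
    return M


def load_config(path) -> dict:
    """YAML build config; recognised keys: nodes_per_edge, kappa, kappa_mode,
    max_dim."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {"nodes_per_edge", "kappa", "kappa_mode", "max_dim"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
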