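"""Shared fixtures: tiny hand-written PDB texts and small synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

from prefint.model_io import Residue, SoluteStructure, SolventTrajectory
from prefint.synthetic import ScenarioSpec, generate_system


def _pdb_line(serial, name, resname, chain, resid, x, y, z, element, record="ATOM"):
    return (
        f"{record:<6s}{serial:5d} {name:<4s} {resname:<3s} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


@pytest.fixture
def toy_pdb_text() -> str:
    """3 residues (chains A, A, B), 9 atoms, orthodox PDB records."""
    lines = []
    serial = 1
    atoms = [
        ("A", 1, "ALA", [("N", "N", 0.0, 0.0, 0.0), ("CA", "C", 1.5, 0.0, 0.0),
                          ("O", "O", 2.2, 1.1, 0.0)]),
        ("A", 2, "GLY", [("N", "N", 4.0, 0.0, 0.0), ("CA", "C", 5.5, 0.0, 0.0),
                          ("O", "O", 6.2, 1.1, 0.0)]),
        ("B", 1, "SER", [("N", "N", 0.0, 6.0, 0.0), ("CA", "C", 1.5, 6.0, 0.0),
                          ("OG", "O", 2.2, 7.1, 0.0)]),
    ]
    for chain, resid, resname, recs in atoms:
        for name, element, x, y, z in recs:
            lines.append(_pdb_line(serial, name, resname, chain, resid, x, y, z, element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_traj_text() -> str:
    """2 frames, 10 single-atom waters + 2 single-atom cosolvents, with box."""
    rng = np.random.default_rng(42)
    frames = []
    lines = ["CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1"]
    pos = rng.random((2, 12, 3)) * 30.0
    for f in range(2):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for m in range(10):
            x, y, z = pos[f, m]
            lines.append(
                _pdb_line(serial, "O", "WAT", "W", m + 1, x, y, z, "O", record="HETATM")
            )
            serial += 1
        for m in range(2):
            x, y, z = pos[f, 10 + m]
            lines.append(
                _pdb_line(serial, "C1", "GOL", "X", m + 1, x, y, z, "C", record="HETATM")
            )
            serial += 1
        lines.append("ENDMDL")
        frames.append(pos[f])
    lines.append("END")
    return "\n".join(lines) + "\n", pos


def single_atom_solute(radius: float = 1.5) -> SoluteStructure:
    return SoluteStructure(
        coords=np.zeros((1, 3)),
        radii=np.array([radius]),
        elements=np.array(["C"]),
        atom_names=np.array(["C1"]),
        residues=(Residue("A", 1, "UNK", 0, 1),),
        label="point solute",
    )


def trajectory_from_points(
    water_frames, cosolvent_frames, box=None
) -> SolventTrajectory:
    """Build a single-heavy-atom-per-molecule trajectory from point arrays."""
    w = np.asarray(water_frames, dtype=float)[:, :, None, :]
    x = np.asarray(cosolvent_frames, dtype=float)[:, :, None, :]
    boxes = None
    if box is not None:
        boxes = np.tile(np.asarray(box, dtype=float), (w.shape[0], 1))
    return SolventTrajectory(water=w, cosolvent=x, boxes=boxes)


@pytest.fixture(scope="session")
def null_system():
    """Uniform-solvent sphere scenario with ground truth (shared, read-only)."""
    spec = ScenarioSpec(
        seed=7, geometry="sphere", atoms_per_blob=12, blob_radius=3.0,
        box=(32.0, 32.0, 32.0), n_water=300, n_cosolvent=32, n_frames=150,
    )
    return generate_system(spec, n_mc=150_000)
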