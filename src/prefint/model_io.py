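"""Structures, solvent trajectories and PDB import/export.

Conventions used throughout the package:

* coordinates are in Angstrom,
* residue numbering is 1-based as in the source PDB, internal indices are
  0-based,
* solvent hydrogens are dropped on load; all occupancy and distance
  statistics use heavy atoms only,
* when orthorhombic box lengths are present every distance uses the
  minimum-image convention; without a box, boundaries are open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from prefint.radii import DEFAULT_RADII, radius_for

# Amino-acid residue names routed to the solute, never to the solvent.
_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL", "MSE", "UNK",
}

DEFAULT_WATER_NAMES = frozenset({"HOH", "TIP3", "TIP3P", "WAT", "SOL", "SPC", "W"})
DEFAULT_COSOLVENT_NAMES = frozenset({"GOL", "GLYC"})


class UnknownElementError(KeyError):
    """An atom's element has no entry in the vdW radius table."""


class SpeciesClassificationError(ValueError):
    """A solvent residue name is not covered by the species map."""


@dataclass(frozen=True)
class SpeciesMap:
    """Maps residue names to the solvent species tags ``water``/``cosolvent``."""

    water: frozenset[str] = DEFAULT_WATER_NAMES
    cosolvent: frozenset[str] = DEFAULT_COSOLVENT_NAMES

    def __post_init__(self) -> None:
        overlap = set(self.water) & set(self.cosolvent)
        if overlap:
            raise ValueError(f"species name sets overlap: {sorted(overlap)}")

    def classify(self, res_name: str) -> str | None:
        name = res_name.strip().upper()
        if name in self.water:
            return "water"
        if name in self.cosolvent:
            return "cosolvent"
        return None

    @classmethod
    def from_config(cls, cfg: Mapping) -> "SpeciesMap":
        water = frozenset(n.upper() for n in cfg.get("water", DEFAULT_WATER_NAMES))
        cosolvent = frozenset(
            n.upper() for n in cfg.get("cosolvent", DEFAULT_COSOLVENT_NAMES)
        )
        return cls(water=water, cosolvent=cosolvent)


@dataclass(frozen=True)
class Residue:
    """One solute residue: identity plus the half-open atom index range."""

    chain: str
    number: int
    name: str
    start: int
    stop: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)


@dataclass
class SoluteStructure:
    """Rigid solute: atom coordinates, vdW radii and residue segmentation."""

    coords: np.ndarray            # (n_atoms, 3) float, Angstrom
    radii: np.ndarray             # (n_atoms,) float, Angstrom
    elements: np.ndarray          # (n_atoms,) str
    atom_names: np.ndarray        # (n_atoms,) str
    residues: tuple[Residue, ...]
    label: str = ""
    atom_residue: np.ndarray = field(init=False)  # (n_atoms,) residue index

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure contains no solute atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")
        if np.any(self.radii <= 0):
            bad = int(np.argmax(self.radii <= 0))
            raise ValueError(f"non-positive vdW radius for atom index {bad}")
        atom_residue = np.full(n, -1, dtype=int)
        keys = set()
        for i, res in enumerate(self.residues):
            if res.key in keys:
                raise ValueError(f"duplicate residue key {res.key}")
            keys.add(res.key)
            if res.start >= res.stop:
                raise ValueError(f"empty residue {res.key}")
            atom_residue[res.start:res.stop] = i
        if np.any(atom_residue < 0):
            raise ValueError("atoms not covered by residue segmentation")
        self.atom_residue = atom_residue

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_keys(self) -> list[tuple[str, int]]:
        return [r.key for r in self.residues]

    def residue_index(self) -> dict[tuple[str, int], int]:
        return {r.key: i for i, r in enumerate(self.residues)}

    def residue_rank(self) -> np.ndarray:
        """Rank of each residue under (chain, number) order (tie-break order)."""
        order = sorted(range(self.n_residues), key=lambda i: self.residues[i].key)
        rank = np.empty(self.n_residues, dtype=int)
        for r, i in enumerate(order):
            rank[i] = r
        return rank

    def subset_by_chains(self, chains: Iterable[str]) -> "SoluteStructure":
        """New structure containing only residues of the given chains."""
        chains = set(chains)
        coords, radii, elements, names, residues = [], [], [], [], []
        pos = 0
        for res in self.residues:
            if res.chain not in chains:
                continue
            n = res.stop - res.start
            coords.append(self.coords[res.start:res.stop])
            radii.append(self.radii[res.start:res.stop])
            elements.append(self.elements[res.start:res.stop])
            names.append(self.atom_names[res.start:res.stop])
            residues.append(Residue(res.chain, res.number, res.name, pos, pos + n))
            pos += n
        if not residues:
            raise ValueError(f"no residues on chains {sorted(chains)}")
        return SoluteStructure(
            coords=np.concatenate(coords),
            radii=np.concatenate(radii),
            elements=np.concatenate(elements),
            atom_names=np.concatenate(names),
            residues=tuple(residues),
            label=self.label,
        )


@dataclass(frozen=True)
class Frame:
    """One solvent frame: heavy-atom coordinates per species plus the box."""

    water: np.ndarray       # (N_w, apm_w, 3)
    cosolvent: np.ndarray   # (N_x, apm_x, 3)
    box: np.ndarray | None  # (3,) orthorhombic lengths or None


@dataclass
class SolventTrajectory:
    """Frames of water and cosolvent heavy-atom coordinates.

    Molecule counts and atom ordering are constant across frames; this is
    validated at construction.
    """

    water: np.ndarray              # (F, N_w, apm_w, 3)
    cosolvent: np.ndarray          # (F, N_x, apm_x, 3)
    boxes: np.ndarray | None = None  # (F, 3) or None
    frame_spacing_ns: float | None = None

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=float)
        self.cosolvent = np.asarray(self.cosolvent, dtype=float)
        if self.water.ndim != 4 or self.cosolvent.ndim != 4:
            raise ValueError("species arrays must have shape (F, N, apm, 3)")
        if self.water.shape[0] != self.cosolvent.shape[0]:
            raise ValueError("water and cosolvent frame counts differ")
        if not np.all(np.isfinite(self.water)) or not np.all(
            np.isfinite(self.cosolvent)
        ):
            raise ValueError("non-finite solvent coordinates")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (self.n_frames, 3):
                raise ValueError("boxes must have shape (n_frames, 3)")
            if np.any(self.boxes <= 0):
                raise ValueError("non-positive box lengths")

    @property
    def n_frames(self) -> int:
        return self.water.shape[0]

    @property
    def n_water(self) -> int:
        return self.water.shape[1]

    @property
    def n_cosolvent(self) -> int:
        return self.cosolvent.shape[1]

    def frame(self, i: int) -> Frame:
        box = None if self.boxes is None else self.boxes[i]
        return Frame(water=self.water[i], cosolvent=self.cosolvent[i], box=box)


def _element_of(atom_name: str, element: str) -> str:
    el = element.strip()
    if el:
        return el.upper()
    name = atom_name.strip().lstrip("0123456789")
    if len(name) >= 2 and name[:2].upper() in DEFAULT_RADII and name[0] not in "CHNOPS":
        return name[:2].upper()
    return name[:1].upper()


def _read_pdb(source) -> struc.AtomArrayStack:
    """Read a (multi-model) PDB from a path, text, or file-like object."""
    if isinstance(source, (str, Path)) and "\n" in str(source):
        pdb = PDBFile.read(io.StringIO(str(source)))
    else:
        pdb = PDBFile.read(source)
    arr = pdb.get_structure(extra_fields=["b_factor"])
    if isinstance(arr, struc.AtomArray):
        arr = struc.stack([arr])
    return arr


def load_structure(
    source,
    radii_overrides: Mapping[str, float] | None = None,
    species_map: SpeciesMap | None = None,
    label: str = "",
) -> SoluteStructure:
    """Load the solute (protein) atoms of a PDB file.

    Solvent records (residue names covered by the species map) are ignored
    here; they belong to trajectory loading.  Every element must have a vdW
    radius in the default table or in ``radii_overrides``.
    """
    smap = species_map or SpeciesMap()
    stack = _read_pdb(source)
    arr = stack[0]
    solvent_mask = np.array(
        [smap.classify(rn) is not None for rn in arr.res_name], dtype=bool
    )
    arr = arr[~solvent_mask]
    if arr.array_length() == 0:
        raise ValueError("PDB source contains no solute atoms")

    coords = np.asarray(arr.coord, dtype=float)
    atom_names = np.asarray(arr.atom_name, dtype=str)
    elements = np.array(
        [_element_of(n, e) for n, e in zip(arr.atom_name, arr.element)], dtype=str
    )
    radii = np.empty(len(coords), dtype=float)
    for i, el in enumerate(elements):
        try:
            radii[i] = radius_for(el, radii_overrides)
        except KeyError:
            raise UnknownElementError(
                f"no vdW radius for element {el!r} "
                f"(atom {atom_names[i]!r} in residue "
                f"{arr.res_name[i]} {arr.chain_id[i]}{arr.res_id[i]})"
            ) from None

    residues: list[Residue] = []
    start = 0
    n = len(coords)
    for i in range(1, n + 1):
        boundary = i == n or (
            arr.chain_id[i] != arr.chain_id[start]
            or arr.res_id[i] != arr.res_id[start]
        )
        if boundary:
            residues.append(
                Residue(
                    chain=str(arr.chain_id[start]),
                    number=int(arr.res_id[start]),
                    name=str(arr.res_name[start]),
                    start=start,
                    stop=i,
                )
            )
            start = i
    return SoluteStructure(
        coords=coords,
        radii=radii,
        elements=elements,
        atom_names=atom_names,
        residues=tuple(residues),
        label=label,
    )


def _box_lengths(stack: struc.AtomArrayStack) -> np.ndarray | None:
    box = stack.box
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    diag = np.stack([np.diag(b) for b in box])
    offdiag = box - np.stack([np.diag(np.diag(b)) for b in box])
    if np.max(np.abs(offdiag)) > 1e-3:
        raise ValueError("only orthorhombic boxes are supported")
    if np.any(diag <= 0):
        return None
    return diag


def _group_molecules(sub: struc.AtomArray) -> list[np.ndarray]:
    """Split a residue-sorted atom selection into per-molecule index groups."""
    groups: list[np.ndarray] = []
    n = sub.array_length()
    start = 0
    for i in range(1, n + 1):
        boundary = i == n or (
            sub.chain_id[i] != sub.chain_id[start]
            or sub.res_id[i] != sub.res_id[start]
        )
        if boundary:
            groups.append(np.arange(start, i))
            start = i
    return groups


def load_trajectory(
    source,
    species_map: SpeciesMap | None = None,
    frame_spacing_ns: float | None = None,
    topology=None,
) -> SolventTrajectory:
    """Load a solvent trajectory and classify molecules by residue name.

    Multi-model PDB files are read natively; binary trajectory formats
    (DCD/XTC/TRR, requiring ``topology``) are routed through MDAnalysis when
    it is installed.  Protein residues in the frames are skipped (the solute
    is rigid and supplied separately); any non-protein residue name that the
    species map cannot classify is an error.
    """
    smap = species_map or SpeciesMap()
    suffix = Path(str(source)).suffix.lower() if isinstance(source, (str, Path)) else ""
    if suffix in {".dcd", ".xtc", ".trr"}:
        return _load_with_mdanalysis(source, topology, smap, frame_spacing_ns)
    stack = _read_pdb(source)
    ref = stack[0]

    heavy = np.char.upper(np.asarray(ref.element, dtype=str)) != "H"
    species_of = np.array([smap.classify(rn) or "" for rn in ref.res_name])
    for i, rn in enumerate(ref.res_name):
        if species_of[i] == "" and rn.upper() not in _AMINO_ACIDS:
            raise SpeciesClassificationError(
                f"residue name {rn!r} is neither protein nor covered by the "
                "species map"
            )

    per_species: dict[str, np.ndarray] = {}
    for tag in ("water", "cosolvent"):
        mask = (species_of == tag) & heavy
        sub = ref[mask]
        groups = _group_molecules(sub)
        if groups:
            sizes = {len(g) for g in groups}
            if len(sizes) != 1:
                raise ValueError(
                    f"inconsistent heavy-atom count per {tag} molecule: {sorted(sizes)}"
                )
            apm = sizes.pop()
            idx = np.flatnonzero(mask)
            coords = stack.coord[:, idx, :]  # (F, n_atoms, 3)
            per_species[tag] = coords.reshape(
                stack.stack_depth(), len(groups), apm, 3
            )
        else:
            per_species[tag] = np.zeros((stack.stack_depth(), 0, 1, 3))

    boxes = _box_lengths(stack)
    return SolventTrajectory(
        water=per_species["water"],
        cosolvent=per_species["cosolvent"],
        boxes=boxes,
        frame_spacing_ns=frame_spacing_ns,
    )


def _load_with_mdanalysis(source, topology, smap, frame_spacing_ns):
    import MDAnalysis as mda

    if topology is None:
        raise ValueError("binary trajectory formats require a topology file")
    u = mda.Universe(str(topology), str(source))
    not_h = u.select_atoms("not element H") if hasattr(u.atoms, "elements") else (
        u.select_atoms("not name H*")
    )
    groups = {"water": [], "cosolvent": []}
    for res in not_h.residues:
        tag = smap.classify(res.resname)
        if tag is None:
            if res.resname.upper() not in _AMINO_ACIDS:
                raise SpeciesClassificationError(
                    f"residue name {res.resname!r} is neither protein nor "
                    "covered by the species map"
                )
            continue
        groups[tag].append(res.atoms.intersection(not_h).indices)
    frames = {"water": [], "cosolvent": []}
    boxes = []
    for ts in u.trajectory:
        dims = ts.dimensions
        boxes.append(dims[:3] if dims is not None and np.all(dims[:3] > 0) else None)
        for tag in groups:
            if groups[tag]:
                frames[tag].append(
                    np.stack([ts.positions[idx] for idx in groups[tag]])
                )
            else:
                frames[tag].append(np.zeros((0, 1, 3)))
    use_box = all(b is not None for b in boxes) and len(boxes) > 0
    return SolventTrajectory(
        water=np.stack(frames["water"]),
        cosolvent=np.stack(frames["cosolvent"]),
        boxes=np.stack(boxes) if use_box else None,
        frame_spacing_ns=frame_spacing_ns,
    )


def _structure_to_atom_array(
    structure: SoluteStructure, b_factor: np.ndarray
) -> struc.AtomArray:
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    for i, res in enumerate(structure.residues):
        arr.chain_id[res.start:res.stop] = res.chain
        arr.res_id[res.start:res.stop] = res.number
        arr.res_name[res.start:res.stop] = res.name
    arr.atom_name = structure.atom_names
    arr.element = structure.elements
    arr.hetero[:] = False
    arr.set_annotation("b_factor", b_factor.astype(float))
    return arr


def export_residue_coloring(
    structure: SoluteStructure,
    values: Mapping[tuple[str, int], float],
    path=None,
) -> str:
    """Write the structure with a per-residue value in the B-factor column.

    Every atom of a residue carries the residue's value (2-decimal fixed
    width, the PDB temperature-factor field); residues absent from ``values``
    carry 0.  Intended for coloring residue-level maps such as per-residue
    delta-Gamma in a molecular viewer.
    """
    index = structure.residue_index()
    for key in values:
        if key not in index:
            raise KeyError(f"residue {key} not present in structure")
    b = np.zeros(structure.n_atoms)
    for key, val in values.items():
        res = structure.residues[index[key]]
        b[res.start:res.stop] = float(val)
    arr = _structure_to_atom_array(structure, b)
    pdb = PDBFile()
    pdb.set_structure(arr)
    text = "\n".join(pdb.lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_residue_coloring(source) -> dict[tuple[str, int], float]:
    """Recover per-residue values written by :func:`export_residue_coloring`."""
    stack = _read_pdb(source)
    arr = stack[0]
    out: dict[tuple[str, int], float] = {}
    for chain, num, b in zip(arr.chain_id, arr.res_id, arr.b_factor):
        out.setdefault((str(chain), int(num)), float(b))
    return out


def write_structure_pdb(structure: SoluteStructure, path) -> None:
    """Write the bare solute structure (B-factors zero)."""
    export_residue_coloring(structure, {}, path)


def write_trajectory_pdb(
    trajectory: SolventTrajectory,
    path,
    water_name: str = "WAT",
    cosolvent_name: str = "GOL",
) -> None:
    """Write a multi-model PDB of the solvent heavy atoms (fixture dialect).

    Waters go on chain W, cosolvent molecules on chain X, one residue per
    molecule.  A CRYST1 record is emitted when box lengths are present.
    """
    lines: list[str] = []
    if trajectory.boxes is not None:
        a, b, c = trajectory.boxes[0]
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1"
        )
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        frame = trajectory.frame(f)
        for tag, coords, resname, chain, el in (
            ("water", frame.water, water_name, "W", "O"),
            ("cosolvent", frame.cosolvent, cosolvent_name, "X", "C"),
        ):
            for m in range(coords.shape[0]):
                for a_i in range(coords.shape[1]):
                    x, y, z = coords[m, a_i]
                    name = el if coords.shape[1] == 1 else f"{el}{a_i + 1}"
                    lines.append(
                        f"HETATM{serial % 100000:5d} {name:<4s} {resname:<3s} "
                        f"{chain}{(m % 9999) + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
                    )
                    serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
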