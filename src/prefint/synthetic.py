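"""Synthetic solvent configurations around toy solutes with known truth.

The generator emulates the mechanisms that drive association-induced
solvation changes — cosolvent enrichment or exclusion in the solvation
shell, dewetted (dry or cosolvent-free) protein-protein contact regions, and
peripheral cosolvent-binding patches — around rigid pseudo-atom solutes, so
that every estimator in the package can be validated against ground truth
without any external data.

Solvent placement is by rejection sampling: uniform proposals in the box are
rejected inside the solute hard core and accepted with probability
proportional to the enrichment factor of the region they fall in (the
maximum factor maps to probability 1).  Frames are i.i.d. by default; an
AR(1) mode re-samples each molecule with probability (1 - rho) per frame,
which gives region-occupancy statistics a lag-1 autocorrelation of rho and
exists to validate block-error estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from prefint.model_io import Residue, SoluteStructure, SolventTrajectory
from prefint.shells import SoluteSurface, gamma_from_counts


@dataclass(frozen=True)
class Dewetting:
    """Cylindrical exclusion region along the contact axis (x) at the box
    center; factors multiply the per-species acceptance there."""

    radius: float = 6.0
    half_length: float = 6.0
    factor_water: float = 1.0
    factor_cosolvent: float = 0.0  # total cosolvent exclusion by default


@dataclass(frozen=True)
class Patch:
    """Spherical enrichment region around one residue's pseudo-atom."""

    chain: str
    residue: int
    radius: float = 3.0
    factor_cosolvent: float = 6.0
    factor_water: float = 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic system; identical spec + seed gives
    bit-identical output."""

    seed: int
    geometry: str = "two_blob"        # "two_blob" | "sphere"
    atoms_per_blob: int = 12
    blob_radius: float = 3.0
    atom_radius: float = 1.6
    gap: float = 2.0                  # surface gap between blobs (two_blob)
    box: tuple[float, float, float] = (36.0, 36.0, 36.0)
    n_water: int = 400
    n_cosolvent: int = 43             # ~6 molal mole ratio vs 400 waters
    cosolvent_atoms: int = 1          # heavy atoms per cosolvent molecule
    shell_width: float = 5.0
    shell_factor_water: float = 1.0
    shell_factor_cosolvent: float = 1.0
    dewetting: Dewetting | None = None
    patch: Patch | None = None
    patch_in_free: bool = False
    n_frames: int = 200
    frame_model: str = "iid"          # "iid" | "ar1"
    ar1_rho: float = 0.0
    sphere_chain: str = "A"
    sphere_center: tuple[float, float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.geometry not in ("two_blob", "sphere"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.frame_model not in ("iid", "ar1"):
            raise ValueError(f"unknown frame model {self.frame_model!r}")
        for name in (
            "shell_factor_water", "shell_factor_cosolvent",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_water < 2:
            raise ValueError("need at least 2 waters (one must remain in bulk)")

    def free_spec(self, side: str, n_frames: int | None = None) -> "ScenarioSpec":
        """Spec of the free-state counterpart of one blob of a complex.

        The blob keeps its absolute position, chain id and residue numbers;
        contact effects (dewetting, and the patch unless ``patch_in_free``)
        are removed, mirroring the free/associated comparison.
        """
        if self.geometry != "two_blob":
            raise ValueError("free_spec applies to two_blob complexes")
        if side not in ("A", "B"):
            raise ValueError("side must be 'A' or 'B'")
        center = _blob_centers(self)[0 if side == "A" else 1]
        keep_patch = (
            self.patch
            if (self.patch_in_free and self.patch and self.patch.chain == side)
            else None
        )
        return replace(
            self,
            geometry="sphere",
            sphere_chain=side,
            sphere_center=tuple(center),
            dewetting=None,
            patch=keep_patch,
            seed=self.seed * 4 + (1 if side == "A" else 2),
            n_frames=self.n_frames if n_frames is None else n_frames,
            label=f"{self.label}:free{side}" if self.label else f"free{side}",
        )


@dataclass
class GroundTruth:
    """Generator-side expectations, estimated by Monte-Carlo integration of
    the sampling density with a seed independent of the trajectory."""

    spec: ScenarioSpec
    cutoff: float
    n_mc: int
    residue_keys: list[tuple[str, int]]
    p_local_water: np.ndarray      # per-residue local probability, water
    p_local_cosolvent: np.ndarray
    expected_gamma: float
    expected_gamma_residue: dict[tuple[str, int], float]

    def expected_regional_gamma(self, keys) -> float:
        return float(sum(self.expected_gamma_residue[k] for k in keys))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit-sphere directions (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _blob_centers(spec: ScenarioSpec) -> np.ndarray:
    c = np.asarray(spec.box) / 2.0
    half = spec.blob_radius + spec.atom_radius + spec.gap / 2.0
    return np.array([c - [half, 0, 0], c + [half, 0, 0]])


def _blob_atoms(spec: ScenarioSpec, center: np.ndarray) -> np.ndarray:
    n = spec.atoms_per_blob
    pts = [center]
    if n > 1:
        pts.append(center + spec.blob_radius * _fibonacci_sphere(n - 1))
    return np.vstack(pts) if n > 1 else np.array(pts)


def build_structure(spec: ScenarioSpec) -> SoluteStructure:
    """Deterministic pseudo-atom solute for a scenario (one residue per atom)."""
    if spec.geometry == "two_blob":
        centers = _blob_centers(spec)
        blobs = [("A", _blob_atoms(spec, centers[0])), ("B", _blob_atoms(spec, centers[1]))]
    else:
        center = (
            np.asarray(spec.sphere_center)
            if spec.sphere_center is not None
            else np.asarray(spec.box) / 2.0
        )
        blobs = [(spec.sphere_chain, _blob_atoms(spec, center))]
    coords, residues = [], []
    pos = 0
    for chain, atoms in blobs:
        for i, xyz in enumerate(atoms):
            coords.append(xyz)
            residues.append(Residue(chain, i + 1, "UNK", pos, pos + 1))
            pos += 1
    coords = np.array(coords)
    n = len(coords)
    return SoluteStructure(
        coords=coords,
        radii=np.full(n, spec.atom_radius),
        elements=np.array(["C"] * n),
        atom_names=np.array([f"C{i + 1}" for i in range(n)]),
        residues=tuple(residues),
        label=spec.label or spec.geometry,
    )


class _Density:
    """Acceptance probability field of the rejection sampler."""

    def __init__(self, spec: ScenarioSpec, structure: SoluteStructure):
        self.spec = spec
        self.surface = SoluteSurface(structure, box=np.asarray(spec.box))
        self.box_center = np.asarray(spec.box) / 2.0
        if spec.patch is not None:
            idx = structure.residue_index()
            key = (spec.patch.chain, spec.patch.residue)
            if key not in idx:
                raise ValueError(f"patch residue {key} not in solute")
            res = structure.residues[idx[key]]
            self.patch_center = structure.coords[res.start]
        else:
            self.patch_center = None
        self.f_max = {
            s: max(
                1.0,
                getattr(spec, f"shell_factor_{s}"),
                getattr(spec.patch, f"factor_{s}") if spec.patch else 0.0,
                getattr(spec.dewetting, f"factor_{s}") if spec.dewetting else 0.0,
            )
            for s in ("water", "cosolvent")
        }

    def factors(self, pts: np.ndarray, species: str) -> np.ndarray:
        spec = self.spec
        sd = self.surface.surface_distance(pts)
        f = np.ones(len(pts))
        f[sd <= spec.shell_width] = getattr(spec, f"shell_factor_{species}")
        if self.patch_center is not None:
            mask = np.linalg.norm(pts - self.patch_center, axis=1) <= spec.patch.radius
            f[mask] = getattr(spec.patch, f"factor_{species}")
        if spec.dewetting is not None:
            dw = spec.dewetting
            radial = np.linalg.norm(pts[:, 1:] - self.box_center[1:], axis=1)
            axial = np.abs(pts[:, 0] - self.box_center[0])
            mask = (radial <= dw.radius) & (axial <= dw.half_length)
            f[mask] = getattr(dw, f"factor_{species}")
        f[sd < 0] = 0.0  # hard core
        return f

    def acceptance(self, pts: np.ndarray, species: str) -> np.ndarray:
        return self.factors(pts, species) / self.f_max[species]


def _sample_points(
    n: int, density: _Density, species: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw exactly n points from the scenario density by rejection."""
    box = np.asarray(density.spec.box)
    out: list[np.ndarray] = []
    need = n
    tries = 0
    while need > 0:
        batch = max(1024, 4 * need)
        prop = rng.random((batch, 3)) * box
        acc = prop[rng.random(batch) < density.acceptance(prop, species)]
        out.append(acc[:need])
        need -= len(acc[:need])
        tries += 1
        if tries > 200:
            raise RuntimeError(
                "rejection sampling is not converging; the acceptance region "
                "is too small for the requested molecule counts"
            )
    return np.concatenate(out)


def generate_system(
    spec: ScenarioSpec,
    ground_truth: bool = True,
    truth_cutoff: float | None = None,
    n_mc: int = 120_000,
) -> tuple[SoluteStructure, SolventTrajectory, GroundTruth | None]:
    """Generate (structure, trajectory, truth) for a scenario.

    Waters are single heavy pseudo-atoms; cosolvent molecules carry
    ``spec.cosolvent_atoms`` heavy atoms placed as a rigid triad of 1.4 A
    bond length around the sampled center (exercising the any-atom minimum
    distance rule).  Molecule counts are exact in every frame.
    """
    structure = build_structure(spec)
    density = _Density(spec, structure)
    rng = np.random.default_rng(spec.seed)
    F = spec.n_frames
    water = np.empty((F, spec.n_water, 1, 3))
    apm_x = spec.cosolvent_atoms
    cosolvent = np.empty((F, spec.n_cosolvent, apm_x, 3))

    def cosolvent_atoms_from_centers(centers: np.ndarray) -> np.ndarray:
        if apm_x == 1:
            return centers[:, None, :]
        offsets = 1.4 * _fibonacci_sphere(apm_x - 1)
        return np.concatenate(
            [centers[:, None, :], centers[:, None, :] + offsets[None, :, :]], axis=1
        )

    w_prev = x_prev = None
    for f in range(F):
        if f == 0 or spec.frame_model == "iid":
            w = _sample_points(spec.n_water, density, "water", rng)
            x = _sample_points(spec.n_cosolvent, density, "cosolvent", rng)
        else:
            keep_w = rng.random(spec.n_water) < spec.ar1_rho
            keep_x = rng.random(spec.n_cosolvent) < spec.ar1_rho
            w = w_prev.copy()
            x = x_prev.copy()
            n_new_w = int((~keep_w).sum())
            n_new_x = int((~keep_x).sum())
            if n_new_w:
                w[~keep_w] = _sample_points(n_new_w, density, "water", rng)
            if n_new_x:
                x[~keep_x] = _sample_points(n_new_x, density, "cosolvent", rng)
        w_prev, x_prev = w, x
        water[f, :, 0, :] = w
        cosolvent[f] = cosolvent_atoms_from_centers(x)

    boxes = np.tile(np.asarray(spec.box, dtype=float), (F, 1))
    trajectory = SolventTrajectory(water=water, cosolvent=cosolvent, boxes=boxes)
    truth = None
    if ground_truth:
        truth = compute_ground_truth(
            spec,
            structure,
            cutoff=truth_cutoff if truth_cutoff is not None else spec.shell_width,
            n_mc=n_mc,
        )
    return structure, trajectory, truth


def compute_ground_truth(
    spec: ScenarioSpec,
    structure: SoluteStructure | None = None,
    cutoff: float = 5.0,
    n_mc: int = 120_000,
) -> GroundTruth:
    """Expected per-residue local occupancies and Gamma by MC integration.

    Points are drawn from the same density as the solvent (with an
    independent seed) and classified exactly like trajectory molecules; the
    expected coefficient uses the plug-in bulk ratio, accurate to O(1/N).
    Cosolvent locality is evaluated at the molecule center (satellite atoms
    enlarge locality slightly; for truth comparisons use single-atom
    cosolvent scenarios).
    """
    structure = structure if structure is not None else build_structure(spec)
    density = _Density(spec, structure)
    rng = np.random.default_rng((spec.seed * 7919 + 13) % (2**31 - 1))
    n_res = structure.n_residues
    p = {}
    for species in ("water", "cosolvent"):
        pts = _sample_points(n_mc, density, species, rng)
        _, res = density.surface.classify_molecules(pts[:, None, :], cutoff)
        p[species] = np.bincount(res[res >= 0], minlength=n_res) / n_mc
    e_nw = spec.n_water * p["water"]
    e_nx = spec.n_cosolvent * p["cosolvent"]
    bulk_ratio = (spec.n_cosolvent - e_nx.sum()) / (spec.n_water - e_nw.sum())
    gamma_res = e_nx - e_nw * bulk_ratio
    keys = structure.residue_keys()
    return GroundTruth(
        spec=spec,
        cutoff=cutoff,
        n_mc=n_mc,
        residue_keys=keys,
        p_local_water=p["water"],
        p_local_cosolvent=p["cosolvent"],
        expected_gamma=float(gamma_res.sum()),
        expected_gamma_residue={k: float(g) for k, g in zip(keys, gamma_res)},
    )


# ---------------------------------------------------------------------------
# canonical study scenarios
# ---------------------------------------------------------------------------


def demo_dewetted_complex(seed: int, n_frames: int = 200) -> ScenarioSpec:
    """Two-blob complex with total cosolvent exclusion at the contact.

    Emulates the glycerol-excluded antibody-antigen contact: the cosolvent is
    modestly shell-enriched everywhere (factor 2) but completely excluded
    from a cylinder spanning the contact region, so association removes
    cosolvent from the local domain and the association-induced change of
    Gamma is negative and confined to the interface.  Solvent composition is
    the 6 molal cosolvent/water mole ratio (~0.108).
    """
    return ScenarioSpec(
        seed=seed,
        geometry="two_blob",
        atoms_per_blob=26,
        blob_radius=5.5,
        gap=1.5,
        box=(58.0, 58.0, 58.0),
        n_water=2400,
        n_cosolvent=260,
        shell_factor_cosolvent=2.0,
        n_frames=n_frames,
        dewetting=Dewetting(
            radius=7.0, half_length=4.0, factor_water=1.0, factor_cosolvent=0.0
        ),
        label="dewetted-contact complex",
    )


def demo_null_sphere(seed: int, n_frames: int = 200) -> ScenarioSpec:
    """Uniform-solvent single blob: E[Gamma] = 0 by symmetry."""
    return ScenarioSpec(
        seed=seed,
        geometry="sphere",
        atoms_per_blob=12,
        blob_radius=3.0,
        box=(32.0, 32.0, 32.0),
        n_water=300,
        n_cosolvent=32,
        n_frames=n_frames,
        label="uniform null",
    )


# ---------------------------------------------------------------------------
# deliberately naive oracles (tests only)
# ---------------------------------------------------------------------------

_MAX_ORACLE_MOLECULES = 500
_MAX_ORACLE_FRAMES = 200


def _check_oracle_size(trajectory: SolventTrajectory) -> None:
    n_mol = trajectory.n_water + trajectory.n_cosolvent
    if n_mol > _MAX_ORACLE_MOLECULES or trajectory.n_frames > _MAX_ORACLE_FRAMES:
        raise ValueError(
            "instance too large for the brute-force oracle "
            f"({n_mol} molecules, {trajectory.n_frames} frames)"
        )


def _brute_molecule_distances(structure, coords, box):
    """Per-molecule (min surface distance, tie-broken residue index) by
    all-pairs evaluation with no spatial indexing."""
    n_mol = coords.shape[0]
    dists = np.empty(n_mol)
    res_idx = np.empty(n_mol, dtype=int)
    keys = structure.residue_keys()
    for m in range(n_mol):
        delta = coords[m][:, None, :] - structure.coords[None, :, :]
        if box is not None:
            delta -= box * np.round(delta / box)
        d = np.linalg.norm(delta, axis=2) - structure.radii[None, :]
        dmin = d.min()
        dists[m] = dmin
        cand_atoms = np.unique(np.nonzero(d <= dmin + 1e-9)[1])
        cand_res = {int(structure.atom_residue[a]) for a in cand_atoms}
        res_idx[m] = min(cand_res, key=lambda i: keys[i])
    return dists, res_idx


def brute_force_classify(structure, frame, cutoff: float = 5.0):
    """Oracle counterpart of classify_frame (all-pairs, loops)."""
    out = {}
    for tag, coords in (("water", frame.water), ("cosolvent", frame.cosolvent)):
        d, r = _brute_molecule_distances(structure, coords, frame.box)
        local = d <= cutoff
        r = np.where(local, r, -1)
        out[tag] = (d, r)
    return out


def brute_force_gamma(
    structure: SoluteStructure,
    trajectory: SolventTrajectory,
    cutoff: float = 5.0,
) -> np.ndarray:
    """Per-frame Gamma by exhaustive all-pairs recounting (tests only)."""
    _check_oracle_size(trajectory)
    F = trajectory.n_frames
    n_x_loc = np.empty(F)
    n_w_loc = np.empty(F)
    for f in range(F):
        frame = trajectory.frame(f)
        res = brute_force_classify(structure, frame, cutoff)
        n_w_loc[f] = int((res["water"][0] <= cutoff).sum())
        n_x_loc[f] = int((res["cosolvent"][0] <= cutoff).sum())
    return gamma_from_counts(
        n_x_loc, n_w_loc, trajectory.n_cosolvent, trajectory.n_water
    )
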