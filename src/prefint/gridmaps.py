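"""Volumetric solvent occupancy maps, preferential-solvation classification
and high-occupancy hydration sites.

Occupancy grids count solvent heavy atoms per voxel over the trajectory.
The bulk reference composition is measured in the region farther than a
margin (default 8 A) from the solute vdW surface, i.e. safely outside the
local solvation domain.  A voxel is preferentially solvated by the cosolvent
when its cosolvent/water occupancy ratio exceeds the bulk ratio by a fold
factor, and by water in the symmetric case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from prefint.model_io import SoluteStructure, SolventTrajectory
from prefint.shells import SoluteSurface

# classification codes
WATER_PREFERRED = -1
NEUTRAL = 0
COSOLVENT_PREFERRED = 1
UNDERSAMPLED = 2


@dataclass
class ConcentrationGrid:
    """Per-species occupancy counts on a regular 3D grid."""

    origin: np.ndarray        # (3,) A, lower corner of voxel (0,0,0)
    spacing: float            # A, cubic voxels
    shape: tuple[int, int, int]
    counts: dict[str, np.ndarray]   # species tag -> (nx, ny, nz) int counts
    n_frames: int
    bulk_density: dict[str, float]  # molecules (heavy atoms) per A^3
    bulk_margin: float              # surface distance defining the bulk shell

    def voxel_volume(self) -> float:
        return self.spacing**3

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ax = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        ay = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        az = self.origin[2] + (np.arange(nz) + 0.5) * self.spacing
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def concentration(self, species: str) -> np.ndarray:
        """Mean local number density (heavy atoms / A^3) per voxel."""
        return self.counts[species] / (self.n_frames * self.voxel_volume())


def _deposit(counts: np.ndarray, pts: np.ndarray, origin, spacing, shape) -> None:
    idx = np.floor((pts - origin) / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    idx = idx[ok]
    if len(idx):
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
        np.add.at(counts.reshape(-1), flat, 1)


def accumulate_grid(
    structure: SoluteStructure,
    trajectory: SolventTrajectory,
    spacing: float = 0.5,
    padding: float = 10.0,
    bulk_margin: float = 8.0,
) -> ConcentrationGrid:
    """Accumulate per-species occupancy over all frames.

    The grid covers the solute bounding box plus ``padding`` on each side;
    voxels use half-open intervals [lo, hi).  Solvent coordinates are wrapped
    into the box when box lengths are present.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = structure.coords.min(axis=0) - padding
    hi = structure.coords.max(axis=0) + padding
    shape = tuple(np.maximum(1, np.ceil((hi - lo) / spacing)).astype(int))
    origin = lo
    counts = {
        "water": np.zeros(shape, dtype=np.int64),
        "cosolvent": np.zeros(shape, dtype=np.int64),
    }
    boxes = trajectory.boxes
    for f in range(trajectory.n_frames):
        frame = trajectory.frame(f)
        for tag, coords in (("water", frame.water), ("cosolvent", frame.cosolvent)):
            pts = coords.reshape(-1, 3)
            if boxes is not None:
                pts = np.mod(pts, frame.box)
            _deposit(counts[tag], pts, origin, spacing, shape)

    # bulk composition from voxels well outside the local solvation domain
    box0 = None if boxes is None else boxes[0]
    surf = SoluteSurface(structure, box=box0)
    centers = np.stack(
        [c.ravel() for c in np.meshgrid(
            origin[0] + (np.arange(shape[0]) + 0.5) * spacing,
            origin[1] + (np.arange(shape[1]) + 0.5) * spacing,
            origin[2] + (np.arange(shape[2]) + 0.5) * spacing,
            indexing="ij",
        )],
        axis=1,
    )
    bulk_mask = surf.surface_distance(centers) > bulk_margin
    if box0 is not None:
        # periodic deposits are wrapped into the canonical cell, so only
        # voxels lying entirely inside it enter the bulk estimate
        bulk_mask &= np.all(
            (centers - spacing / 2 >= -1e-9) & (centers + spacing / 2 <= box0 + 1e-9),
            axis=1,
        )
    n_bulk = int(bulk_mask.sum())
    if n_bulk == 0:
        raise ValueError(
            "no bulk voxels beyond the bulk margin; increase padding"
        )
    vol = n_bulk * spacing**3 * trajectory.n_frames
    bulk_density = {}
    for tag in counts:
        bulk_density[tag] = float(counts[tag].reshape(-1)[bulk_mask].sum()) / vol
    return ConcentrationGrid(
        origin=np.asarray(origin, dtype=float),
        spacing=float(spacing),
        shape=shape,
        counts=counts,
        n_frames=trajectory.n_frames,
        bulk_density=bulk_density,
        bulk_margin=float(bulk_margin),
    )


def classify_preferential(
    grid: ConcentrationGrid, fold: float = 2.0, min_occupancy: int = 20
) -> np.ndarray:
    """Classify voxels by solvation preference relative to the bulk ratio.

    Codes: +1 cosolvent-preferred, -1 water-preferred, 0 neutral,
    2 undersampled (total occupancy below ``min_occupancy``).  A preference
    call additionally requires both species to exceed ``min_occupancy``; the
    classification depends only on occupancy ratios, so it is invariant under
    joint rescaling of both species.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    c_w = grid.counts["water"].astype(float)
    c_x = grid.counts["cosolvent"].astype(float)
    rho_w = grid.bulk_density["water"]
    rho_x = grid.bulk_density["cosolvent"]
    if rho_w <= 0 or rho_x <= 0:
        raise ValueError("bulk densities must be positive for classification")
    bulk_ratio = rho_x / rho_w
    out = np.full(grid.shape, NEUTRAL, dtype=np.int8)
    total = c_w + c_x
    under = total < min_occupancy
    both = (c_w > min_occupancy) & (c_x > min_occupancy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c_w > 0, c_x / np.maximum(c_w, 1e-300), np.inf)
    out[both & (ratio > fold * bulk_ratio)] = COSOLVENT_PREFERRED
    out[both & (ratio < bulk_ratio / fold)] = WATER_PREFERRED
    out[under] = UNDERSAMPLED
    return out


@dataclass(frozen=True)
class HydrationSite:
    center: np.ndarray  # (3,) A
    occupancy: float    # fraction of frames with >=1 water within the radius
    rank: int


def find_hydration_sites(
    grid: ConcentrationGrid,
    trajectory: SolventTrajectory,
    site_radius: float = 1.0,
    min_occupancy_fraction: float = 0.5,
    species: str = "water",
    max_sites: int = 200,
) -> list[HydrationSite]:
    """Detect localized high-occupancy solvent sites.

    Candidate centers are greedy non-overlapping occupancy maxima of the
    species grid (centers at least 2 * site_radius apart).  Each candidate's
    occupancy is the fraction of frames with at least one heavy atom of the
    species within ``site_radius`` of the center; candidates below
    ``min_occupancy_fraction`` are dropped and the rest are ranked by
    occupancy (ties by lexicographic center).
    """
    if site_radius < grid.spacing:
        raise ValueError("site radius must be at least the grid spacing")
    counts = grid.counts[species].astype(float).copy()
    nx, ny, nz = grid.shape
    centers: list[np.ndarray] = []
    # greedy selection on voxel counts
    floor = max(1.0, min_occupancy_fraction * grid.n_frames * 0.05)
    while len(centers) < max_sites:
        flat = int(np.argmax(counts))
        if counts.reshape(-1)[flat] < floor:
            break
        ijk = np.unravel_index(flat, grid.shape)
        center = grid.origin + (np.array(ijk) + 0.5) * grid.spacing
        centers.append(center)
        # suppress the claimed neighborhood
        rad_vox = int(np.ceil(2 * site_radius / grid.spacing)) + 1
        sl = tuple(
            slice(max(0, ijk[d] - rad_vox), min(grid.shape[d], ijk[d] + rad_vox + 1))
            for d in range(3)
        )
        sub_idx = np.moveaxis(
            np.mgrid[sl[0], sl[1], sl[2]], 0, -1
        ).reshape(-1, 3)
        sub_centers = grid.origin + (sub_idx + 0.5) * grid.spacing
        close = np.linalg.norm(sub_centers - center, axis=1) < 2 * site_radius
        flat_idx = np.ravel_multi_index(
            (sub_idx[:, 0], sub_idx[:, 1], sub_idx[:, 2]), grid.shape
        )
        counts.reshape(-1)[flat_idx[close]] = 0.0
    if not centers:
        return []
    centers_arr = np.array(centers)
    hits = np.zeros(len(centers), dtype=int)
    attr = "water" if species == "water" else "cosolvent"
    for f in range(trajectory.n_frames):
        frame = trajectory.frame(f)
        pts = getattr(frame, attr).reshape(-1, 3)
        if len(pts) == 0:
            continue
        tree = cKDTree(pts)
        counts_near = tree.query_ball_point(centers_arr, site_radius,
                                            return_length=True)
        hits += counts_near > 0
    occ = hits / trajectory.n_frames
    keep = [
        (float(o), tuple(np.round(c, 6)), c)
        for o, c in zip(occ, centers_arr)
        if o >= min_occupancy_fraction
    ]
    keep.sort(key=lambda t: (-t[0], t[1]))
    return [
        HydrationSite(center=c, occupancy=o, rank=i + 1)
        for i, (o, _, c) in enumerate(keep)
    ]


def write_dx(values: np.ndarray, origin, spacing: float, path) -> None:
    """Write a scalar field in OpenDX format (z varies fastest)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("grid values must be finite")
    nx, ny, nz = values.shape
    origin = np.asarray(origin, dtype=float)
    lines = [
        "# OpenDX scalar field written by prefint",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}",
        f"delta {spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    flat = values.reshape(-1)  # C order: z fastest, as viewers expect
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read an OpenDX scalar field; returns (values, origin, spacing)."""
    shape = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    in_data = False
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if in_data:
            if s.startswith(("attribute", "object")):
                in_data = False
                continue
            data.extend(float(t) for t in s.split())
            continue
        if s.startswith("object 1"):
            shape = tuple(int(t) for t in s.split()[-3:])
        elif s.startswith("origin"):
            origin = np.array([float(t) for t in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append([float(t) for t in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split()[-3])
            in_data = True
    if shape is None or origin is None or n_items is None:
        raise ValueError("not a valid OpenDX scalar field")
    spacing = float(deltas[0][0])
    values = np.array(data[:n_items]).reshape(shape)
    return values, origin, spacing
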