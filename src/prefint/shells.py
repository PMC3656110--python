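"""Solvation-shell counting and preferential interaction coefficients.

The two-domain model splits the solvent into a local domain — molecules with
at least one heavy atom within a cutoff (default 5 A) of the solute van der
Waals surface — and the bulk remainder.  The instantaneous preferential
interaction coefficient compares the local cosolvent count with the count
expected from the bulk composition:

    Gamma(t) = n_x(t) - n_w(t) * (N_x - n_x(t)) / (N_w - n_w(t))

where n are local counts and N totals per species.  The trajectory mean of
Gamma(t) is the reported coefficient; its standard error comes from block
averaging, which is robust to frame autocorrelation.

Each local molecule is assigned to the residue whose surface it is closest
to (ties broken toward the lowest (chain, residue-number) pair), making the
per-residue coefficients an exact frame-wise partition of the global one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from prefint.model_io import Frame, SoluteStructure, SolventTrajectory

_TIE_TOL = 1e-9


class EmptyBulkError(ValueError):
    """A frame has no bulk water left, so the bulk ratio is undefined."""


@dataclass
class ShellAssignment:
    """Result of classifying one frame against the solute surface."""

    cutoff: float
    water_distance: np.ndarray      # (N_w,) min surface distance per molecule
    water_residue: np.ndarray       # (N_w,) residue index, -1 when not local
    cosolvent_distance: np.ndarray  # (N_x,)
    cosolvent_residue: np.ndarray   # (N_x,)
    counts_water: np.ndarray        # (n_residues,) local waters per residue
    counts_cosolvent: np.ndarray    # (n_residues,)

    @property
    def water_local(self) -> np.ndarray:
        return self.water_distance <= self.cutoff

    @property
    def cosolvent_local(self) -> np.ndarray:
        return self.cosolvent_distance <= self.cutoff

    @property
    def n_water_local(self) -> int:
        return int(self.counts_water.sum())

    @property
    def n_cosolvent_local(self) -> int:
        return int(self.counts_cosolvent.sum())


@dataclass
class GammaEstimate:
    """A preferential interaction coefficient with its per-frame series."""

    mean: float
    se: float
    series: np.ndarray
    cutoff: float
    scope: str  # {"global", "residue", "region"}

    @property
    def n_frames(self) -> int:
        return len(self.series)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    @classmethod
    def from_series(
        cls, series: np.ndarray, cutoff: float, scope: str, min_blocks: int = 4
    ) -> "GammaEstimate":
        series = np.asarray(series, dtype=float)
        return cls(
            mean=float(series.mean()),
            se=block_error(series, min_blocks=min_blocks),
            series=series,
            cutoff=cutoff,
            scope=scope,
        )


class SoluteSurface:
    """Spatial index for exact minimum surface distances to a solute.

    The surface distance of a point is min over solute atoms of
    (center distance - vdW radius).  With box lengths present all distances
    are minimum-image for an orthorhombic box.
    """

    def __init__(self, structure: SoluteStructure, box: np.ndarray | None = None):
        self.structure = structure
        self.box = None if box is None else np.asarray(box, dtype=float)
        coords = structure.coords
        if self.box is not None:
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")
            coords = np.mod(coords, self.box)
        self._coords = coords
        self._radii = structure.radii
        self._rmax = float(structure.radii.max())
        self._tree = cKDTree(coords, boxsize=self.box)
        self._res_rank = structure.residue_rank()
        self._atom_rank = self._res_rank[structure.atom_residue]
        # residue index recoverable from rank
        self._rank_to_res = np.empty(structure.n_residues, dtype=int)
        self._rank_to_res[self._res_rank] = np.arange(structure.n_residues)

    def _delta(self, pts: np.ndarray, atom_idx: np.ndarray) -> np.ndarray:
        d = pts - self._coords[atom_idx]
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        return d

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Exact surface distance for each point."""
        dist, _, _ = self._candidates(points)
        starts = self._point_starts
        return np.minimum.reduceat(dist, starts)

    def _candidates(self, points: np.ndarray):
        """All-candidate arrays guaranteed to contain each point's minimizer.

        The nearest atom *center* bounds the search: any atom that could
        attain a smaller surface distance lies within d_nn + r_max of the
        point.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.box is not None:
            pts = np.mod(pts, self.box)
        d_nn, _ = self._tree.query(pts)
        radius = d_nn + self._rmax + 1e-7
        cand = self._tree.query_ball_point(pts, radius)
        lens = np.array([len(c) for c in cand], dtype=int)
        flat = np.concatenate(cand) if len(cand) else np.empty(0, dtype=int)
        flat = np.asarray(flat, dtype=int)
        pt_idx = np.repeat(np.arange(len(pts)), lens)
        delta = self._delta(pts[pt_idx], flat)
        dist = np.linalg.norm(delta, axis=1) - self._radii[flat]
        self._point_starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
        self._point_lens = lens
        return dist, flat, pt_idx

    def classify_molecules(self, coords: np.ndarray, cutoff: float):
        """Per-molecule (min surface distance, assigned residue index).

        ``coords`` has shape (n_molecules, atoms_per_molecule, 3).  A
        molecule's distance is the minimum over its heavy atoms; the assigned
        residue is the one attaining it, ties resolved toward the lowest
        (chain, residue-number) order.  Residue assignment is only reported
        (index >= 0) for local molecules.
        """
        n_mol, apm = coords.shape[0], coords.shape[1]
        if n_mol == 0:
            return np.empty(0), np.empty(0, dtype=int)
        pts = coords.reshape(-1, 3)
        dist, flat, pt_idx = self._candidates(pts)
        mol_of_cand = pt_idx // apm
        # candidate list is ordered by point, hence by molecule
        change = np.flatnonzero(np.diff(mol_of_cand)) + 1
        starts = np.concatenate(([0], change))
        dmin = np.minimum.reduceat(dist, starts)
        mol_ids = mol_of_cand[starts]
        out_dist = np.empty(n_mol)
        out_dist[mol_ids] = dmin
        # tie-broken residue assignment among candidates at the minimum
        at_min = dist <= out_dist[mol_of_cand] + _TIE_TOL
        ranks = np.where(at_min, self._atom_rank[flat], np.iinfo(np.int64).max)
        best_rank = np.minimum.reduceat(ranks, starts)
        out_res = np.full(n_mol, -1, dtype=int)
        local = out_dist[mol_ids] <= cutoff
        out_res[mol_ids[local]] = self._rank_to_res[best_rank[local]]
        return out_dist, out_res


def classify_frame(
    structure: SoluteStructure, frame: Frame, cutoff: float = 5.0
) -> ShellAssignment:
    """Classify every solvent molecule of one frame as local or bulk."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if frame.water.shape[0] == 0 and frame.cosolvent.shape[0] == 0:
        raise ValueError("frame contains no solvent molecules")
    surf = SoluteSurface(structure, box=frame.box)
    wd, wr = surf.classify_molecules(frame.water, cutoff)
    xd, xr = surf.classify_molecules(frame.cosolvent, cutoff)
    n_res = structure.n_residues
    counts_w = np.bincount(wr[wr >= 0], minlength=n_res)
    counts_x = np.bincount(xr[xr >= 0], minlength=n_res)
    return ShellAssignment(
        cutoff=cutoff,
        water_distance=wd,
        water_residue=wr,
        cosolvent_distance=xd,
        cosolvent_residue=xr,
        counts_water=counts_w,
        counts_cosolvent=counts_x,
    )


def count_trajectory(
    structure: SoluteStructure, trajectory: SolventTrajectory, cutoff: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame, per-residue local counts (water, cosolvent).

    Returns two arrays of shape (n_frames, n_residues).  The spatial index
    is reused across frames when the box is constant.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    F = trajectory.n_frames
    n_res = structure.n_residues
    counts_w = np.zeros((F, n_res), dtype=np.int64)
    counts_x = np.zeros((F, n_res), dtype=np.int64)
    boxes = trajectory.boxes
    const_box = boxes is None or np.allclose(boxes, boxes[0])
    surf = SoluteSurface(structure, box=None if boxes is None else boxes[0]) \
        if const_box else None
    for f in range(F):
        s = surf if const_box else SoluteSurface(structure, box=boxes[f])
        frame = trajectory.frame(f)
        _, wr = s.classify_molecules(frame.water, cutoff)
        _, xr = s.classify_molecules(frame.cosolvent, cutoff)
        counts_w[f] = np.bincount(wr[wr >= 0], minlength=n_res)
        counts_x[f] = np.bincount(xr[xr >= 0], minlength=n_res)
    return counts_w, counts_x


def gamma_from_counts(
    n_x_local: np.ndarray,
    n_w_local: np.ndarray,
    n_x_total: int,
    n_w_total: int,
) -> np.ndarray:
    """Instantaneous Gamma(t) from local counts and totals."""
    n_x_local = np.asarray(n_x_local, dtype=float)
    n_w_local = np.asarray(n_w_local, dtype=float)
    bulk_w = n_w_total - n_w_local
    if np.any(bulk_w < 1):
        bad = int(np.argmax(bulk_w < 1))
        raise EmptyBulkError(f"no bulk water left in frame {bad}")
    return n_x_local - n_w_local * (n_x_total - n_x_local) / bulk_w


def _bulk_ratio(counts_w, counts_x, n_w_total, n_x_total) -> np.ndarray:
    n_w_loc = counts_w.sum(axis=1)
    n_x_loc = counts_x.sum(axis=1)
    bulk_w = n_w_total - n_w_loc
    if np.any(bulk_w < 1):
        bad = int(np.argmax(bulk_w < 1))
        raise EmptyBulkError(f"no bulk water left in frame {bad}")
    return (n_x_total - n_x_loc) / bulk_w


def gamma_global(
    structure: SoluteStructure,
    trajectory: SolventTrajectory,
    cutoff: float = 5.0,
    estimator: str = "instantaneous",
    min_blocks: int = 4,
    counts: tuple[np.ndarray, np.ndarray] | None = None,
) -> GammaEstimate:
    """Global preferential interaction coefficient of the solute.

    ``estimator`` selects the bulk-ratio convention: "instantaneous" uses the
    per-frame bulk composition (default; gives exact frame-wise additivity of
    per-residue coefficients), "ratio-of-means" uses the trajectory-mean
    local counts and must agree within one standard error on well-sampled
    data.
    """
    counts_w, counts_x = counts if counts is not None else count_trajectory(
        structure, trajectory, cutoff
    )
    N_w, N_x = trajectory.n_water, trajectory.n_cosolvent
    n_w_loc = counts_w.sum(axis=1).astype(float)
    n_x_loc = counts_x.sum(axis=1).astype(float)
    if estimator == "instantaneous":
        series = gamma_from_counts(n_x_loc, n_w_loc, N_x, N_w)
    elif estimator == "ratio-of-means":
        bulk_w = N_w - n_w_loc
        if np.any(bulk_w < 1):
            bad = int(np.argmax(bulk_w < 1))
            raise EmptyBulkError(f"no bulk water left in frame {bad}")
        ratio = (N_x - n_x_loc.mean()) / (N_w - n_w_loc.mean())
        series = n_x_loc - n_w_loc * ratio
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return GammaEstimate.from_series(series, cutoff, "global", min_blocks=min_blocks)


def gamma_per_residue(
    structure: SoluteStructure,
    trajectory: SolventTrajectory,
    cutoff: float = 5.0,
    min_blocks: int = 4,
    counts: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[tuple[str, int], GammaEstimate]:
    """Residue-resolved coefficients that sum frame-wise to the global one.

    Gamma_res(t) = n_x,res(t) - n_w,res(t) * B(t) with B(t) the global bulk
    ratio of frame t, so that sum over residues equals the instantaneous
    global Gamma(t) exactly.
    """
    counts_w, counts_x = counts if counts is not None else count_trajectory(
        structure, trajectory, cutoff
    )
    ratio = _bulk_ratio(counts_w, counts_x, trajectory.n_water, trajectory.n_cosolvent)
    series = counts_x - counts_w * ratio[:, None]  # (F, n_residues)
    out: dict[tuple[str, int], GammaEstimate] = {}
    for i, res in enumerate(structure.residues):
        out[res.key] = GammaEstimate.from_series(
            series[:, i], cutoff, "residue", min_blocks=min_blocks
        )
    return out


def block_error(series: np.ndarray, min_blocks: int = 4) -> float:
    """Block-averaged standard error of the mean of a (possibly correlated)
    series.

    Blocks of length n/2^k are formed for increasing k; for each level with
    at least ``min_blocks`` blocks the SE of the block means is computed, and
    the plateau is read as the maximum over the two coarsest admissible
    levels.  The result is floored at half the naive i.i.d. standard error.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 8:
        raise ValueError(f"series too short for block analysis (n={n} < 8)")
    if np.all(series == series[0]):
        return 0.0
    naive = float(series.std(ddof=1)) / np.sqrt(n)
    if naive == 0.0:
        return 0.0
    ses = []
    k = 1
    while True:
        L = n // 2**k
        if L < 1:
            break
        nb = n // L
        if nb >= min_blocks:
            means = series[: nb * L].reshape(nb, L).mean(axis=1)
            ses.append((L, float(means.std(ddof=1)) / np.sqrt(nb)))
        k += 1
    if not ses:
        return naive
    ses.sort(key=lambda t: -t[0])
    plateau = max(se for _, se in ses[:2])
    return max(plateau, naive / 2.0)
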