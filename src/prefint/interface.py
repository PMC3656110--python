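"""Protein-protein interface decomposition of solvation changes.

A complex's residues are split into the interface region inte(D) — residues
with at least one atom within an atom-center distance D of the partner
protein — and the remainder non-inte(D).  Regional coefficients are exact
frame-wise sums of per-residue coefficients, so

    Gamma = Gamma_inte(D) + Gamma_non-inte(D)

holds identically for every D.  The interface distance D* is the smallest
scanned D at which the non-interface regional coefficient no longer differs
significantly (|delta| <= k * SE, SE in quadrature) between the associated
complex and the two free proteins; beyond D* the whole association-induced
solvation change is carried by the interface region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from prefint.model_io import SoluteStructure, SolventTrajectory
from prefint.shells import (
    GammaEstimate,
    count_trajectory,
    gamma_global,
    gamma_per_residue,
)

ResKey = tuple[str, int]


class InterfaceScanError(RuntimeError):
    """No scanned D satisfied the interface criterion; carries the scan."""

    def __init__(self, message: str, scan: pd.DataFrame):
        super().__init__(message)
        self.scan = scan


@dataclass(frozen=True)
class RegionPartition:
    """inte(D)/non-inte(D) split of a complex's residues."""

    D: float
    inte: frozenset[ResKey]
    non_inte: frozenset[ResKey]
    chains_a: frozenset[str]

    def __post_init__(self) -> None:
        if self.inte & self.non_inte:
            raise ValueError("inte and non-inte overlap")


@dataclass(frozen=True)
class DeltaGamma:
    """Gamma(complex) - Gamma(free A) - Gamma(free B) with quadrature SE."""

    value: float
    se: float
    complex_: GammaEstimate
    free_a: GammaEstimate
    free_b: GammaEstimate
    scope: str = "global"


@dataclass
class SolvationSystem:
    """A solute structure paired with its solvent ensemble."""

    structure: SoluteStructure
    trajectory: SolventTrajectory
    label: str = ""

    _counts: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    _counts_cutoff: float | None = field(default=None, repr=False, compare=False)

    def counts(self, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
        if self._counts is None or self._counts_cutoff != cutoff:
            self._counts = count_trajectory(self.structure, self.trajectory, cutoff)
            self._counts_cutoff = cutoff
        return self._counts

    def gamma_global(self, cutoff: float = 5.0, **kw) -> GammaEstimate:
        return gamma_global(
            self.structure, self.trajectory, cutoff, counts=self.counts(cutoff), **kw
        )

    def gamma_per_residue(self, cutoff: float = 5.0, **kw):
        return gamma_per_residue(
            self.structure, self.trajectory, cutoff, counts=self.counts(cutoff), **kw
        )


def interface_residues(
    structure: SoluteStructure, chains_a: Sequence[str], D: float
) -> RegionPartition:
    """Partition a complex into inte(D) and non-inte(D).

    A residue (of either side) is in inte(D) iff any of its atoms lies within
    atom-center distance D of any atom of the other side.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    chains_a = frozenset(chains_a)
    all_chains = {r.chain for r in structure.residues}
    chains_b = all_chains - chains_a
    if not chains_a & all_chains or not chains_b:
        raise ValueError(
            f"chain split {sorted(chains_a)} leaves one side empty "
            f"(structure chains: {sorted(all_chains)})"
        )
    side_a = np.isin(
        np.array([structure.residues[i].chain for i in structure.atom_residue]),
        list(chains_a),
    )
    coords_a, coords_b = structure.coords[side_a], structure.coords[~side_a]
    tree_a, tree_b = cKDTree(coords_a), cKDTree(coords_b)
    d_a, _ = tree_b.query(coords_a)  # per A atom: min distance to B
    d_b, _ = tree_a.query(coords_b)
    atom_min = np.empty(structure.n_atoms)
    atom_min[side_a] = d_a
    atom_min[~side_a] = d_b
    inte, non_inte = set(), set()
    for res in structure.residues:
        if atom_min[res.start:res.stop].min() <= D:
            inte.add(res.key)
        else:
            non_inte.add(res.key)
    return RegionPartition(
        D=float(D),
        inte=frozenset(inte),
        non_inte=frozenset(non_inte),
        chains_a=chains_a,
    )


def build_residue_mapping(
    complex_structure: SoluteStructure,
    free_a: SoluteStructure,
    free_b: SoluteStructure,
    chains_a: Sequence[str],
    overrides: Mapping[ResKey, tuple[str, ResKey]] | None = None,
) -> dict[ResKey, tuple[str, ResKey]]:
    """Map each complex residue to ("A"|"B", residue key in its free state).

    Matching is by (chain, residue number, residue name) equality; renumbered
    structures can be patched with ``overrides``.  The mapping is injective
    per free structure.
    """
    chains_a = set(chains_a)
    by_free = {
        "A": {(r.chain, r.number, r.name): r.key for r in free_a.residues},
        "B": {(r.chain, r.number, r.name): r.key for r in free_b.residues},
    }
    mapping: dict[ResKey, tuple[str, ResKey]] = {}
    used: dict[str, set[ResKey]] = {"A": set(), "B": set()}
    for res in complex_structure.residues:
        if overrides and res.key in overrides:
            side, target = overrides[res.key]
        else:
            side = "A" if res.chain in chains_a else "B"
            ident = (res.chain, res.number, res.name)
            if ident not in by_free[side]:
                raise KeyError(
                    f"complex residue {ident} has no counterpart in free state {side}"
                )
            target = by_free[side][ident]
        if target in used[side]:
            raise ValueError(f"free residue {target} mapped twice (side {side})")
        used[side].add(target)
        mapping[res.key] = (side, target)
    return mapping


def _sum_series(
    per_res: Mapping[ResKey, GammaEstimate], keys, cutoff, scope, min_blocks=4
) -> GammaEstimate:
    keys = list(keys)
    if not per_res:
        raise ValueError("empty per-residue map")
    n = next(iter(per_res.values())).n_frames
    series = np.zeros(n)
    for key in keys:
        if key not in per_res:
            raise KeyError(f"residue {key} missing from per-residue map")
        series += per_res[key].series
    return GammaEstimate.from_series(series, cutoff, scope, min_blocks=min_blocks)


def regional_gamma(
    per_residue: Mapping[ResKey, GammaEstimate],
    partition: RegionPartition,
    min_blocks: int = 4,
) -> tuple[GammaEstimate, GammaEstimate]:
    """(Gamma_inte, Gamma_non-inte) as exact frame-wise sums of members."""
    cutoff = next(iter(per_residue.values())).cutoff
    inte = _sum_series(per_residue, partition.inte, cutoff, "region", min_blocks)
    non = _sum_series(per_residue, partition.non_inte, cutoff, "region", min_blocks)
    return inte, non


def delta_gamma(
    complex_: GammaEstimate, free_a: GammaEstimate, free_b: GammaEstimate,
    scope: str = "global",
) -> DeltaGamma:
    """Association-induced change of Gamma, SEs combined in quadrature."""
    value = complex_.mean - free_a.mean - free_b.mean
    se = float(np.sqrt(complex_.se**2 + free_a.se**2 + free_b.se**2))
    return DeltaGamma(
        value=float(value), se=se,
        complex_=complex_, free_a=free_a, free_b=free_b, scope=scope,
    )


def _free_regional(per_res_free, mapping, complex_keys, side, cutoff, min_blocks):
    keys = [mapping[k][1] for k in complex_keys if mapping[k][0] == side]
    if not keys:
        n = next(iter(per_res_free.values())).n_frames
        return GammaEstimate.from_series(
            np.zeros(n), cutoff, "region", min_blocks=min_blocks
        )
    return _sum_series(per_res_free, keys, cutoff, "region", min_blocks)


def determine_interface_distance(
    complex_system: SolvationSystem,
    free_a: SolvationSystem,
    free_b: SolvationSystem,
    chains_a: Sequence[str],
    d_grid: Sequence[float] = tuple(range(3, 13)),
    k: float = 1.0,
    cutoff: float = 5.0,
    mapping_overrides=None,
    min_blocks: int = 4,
) -> tuple[float, pd.DataFrame]:
    """Scan D and return (D*, scan report).

    D* is the smallest scanned D at which |delta Gamma_non-inte(D)| <= k * SE,
    i.e. at which the non-interface surface no longer feels the association.
    The report contains one row per scanned D regardless of the outcome.
    """
    d_grid = sorted(d_grid)
    per_c = complex_system.gamma_per_residue(cutoff, min_blocks=min_blocks)
    per_a = free_a.gamma_per_residue(cutoff, min_blocks=min_blocks)
    per_b = free_b.gamma_per_residue(cutoff, min_blocks=min_blocks)
    mapping = build_residue_mapping(
        complex_system.structure, free_a.structure, free_b.structure,
        chains_a, overrides=mapping_overrides,
    )
    rows = []
    dstar = None
    for D in d_grid:
        part = interface_residues(complex_system.structure, chains_a, D)
        g_inte_c, g_non_c = regional_gamma(per_c, part, min_blocks=min_blocks)
        g_non_a = _free_regional(per_a, mapping, part.non_inte, "A", cutoff, min_blocks)
        g_non_b = _free_regional(per_b, mapping, part.non_inte, "B", cutoff, min_blocks)
        dg = delta_gamma(g_non_c, g_non_a, g_non_b, scope="non-inte")
        passed = abs(dg.value) <= k * dg.se
        rows.append(
            {
                "D": D,
                "n_inte": len(part.inte),
                "gamma_inte_complex": g_inte_c.mean,
                "gamma_noninte_complex": g_non_c.mean,
                "gamma_noninte_free_a": g_non_a.mean,
                "gamma_noninte_free_b": g_non_b.mean,
                "delta_noninte": dg.value,
                "se": dg.se,
                "pass": passed,
            }
        )
        if passed and dstar is None:
            dstar = float(D)
    scan = pd.DataFrame(rows)
    if dstar is None:
        raise InterfaceScanError(
            "no scanned D satisfies |delta Gamma_non-inte| <= k*SE", scan
        )
    return dstar, scan


@dataclass(frozen=True)
class ResidueDelta:
    value: float
    se: float
    significant: bool


def residue_delta_map(
    per_res_complex: Mapping[ResKey, GammaEstimate],
    per_res_free_a: Mapping[ResKey, GammaEstimate],
    per_res_free_b: Mapping[ResKey, GammaEstimate],
    mapping: Mapping[ResKey, tuple[str, ResKey]],
    k: float = 2.0,
) -> dict[ResKey, ResidueDelta]:
    """Per-residue association-induced change of the local coefficient.

    delta = Gamma_res(complex) - Gamma_res(free counterpart); significant iff
    |delta| > k * quadrature SE.  The values feed
    :func:`prefint.model_io.export_residue_coloring` (positive: preferential
    cosolvent binding gained on association; negative: lost).
    """
    free = {"A": per_res_free_a, "B": per_res_free_b}
    out: dict[ResKey, ResidueDelta] = {}
    for key, g_c in per_res_complex.items():
        if key not in mapping:
            raise KeyError(f"complex residue {key} missing from mapping")
        side, free_key = mapping[key]
        if free_key not in free[side]:
            raise KeyError(f"free residue {free_key} missing from side {side}")
        g_f = free[side][free_key]
        value = g_c.mean - g_f.mean
        se = float(np.hypot(g_c.se, g_f.se))
        out[key] = ResidueDelta(
            value=float(value), se=se, significant=bool(abs(value) > k * se)
        )
    return out
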