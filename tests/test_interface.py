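"""Interface partition, regional coefficients and association deltas."""

import numpy as np
import pytest

from prefint.interface import (
    InterfaceScanError,
    RegionPartition,
    SolvationSystem,
    build_residue_mapping,
    delta_gamma,
    determine_interface_distance,
    interface_residues,
    regional_gamma,
    residue_delta_map,
)
from prefint.model_io import Residue, SoluteStructure
from prefint.shells import GammaEstimate, gamma_global, gamma_per_residue
from prefint.synthetic import Patch, ScenarioSpec, build_structure, generate_system


def _two_chain_toy() -> SoluteStructure:
    """Two 3-residue chains; exactly one contact pair at 4.2 A, next at 6.8 A."""
    coords = np.array(
        [
            # chain A, residues 1..3 (one atom each)
            [0.0, 0.0, 0.0],
            [0.0, 4.0, 0.0],
            [0.0, 8.0, 0.0],
            # chain B
            [4.2, 0.0, 0.0],   # 4.2 from A:1
            [6.8, 4.0, 0.0],   # 6.8 from A:2
            [9.0, 8.0, 0.0],
        ]
    )
    residues = tuple(
        Residue(c, i + 1, "UNK", j, j + 1)
        for j, (c, i) in enumerate([("A", 0), ("A", 1), ("A", 2),
                                    ("B", 0), ("B", 1), ("B", 2)])
    )
    return SoluteStructure(
        coords=coords,
        radii=np.full(6, 1.5),
        elements=np.array(["C"] * 6),
        atom_names=np.array([f"C{i}" for i in range(6)]),
        residues=residues,
    )


def _brute_interface(structure, chains_a, D):
    """Independent all-pairs recomputation of the inte(D) set."""
    chains_a = set(chains_a)
    inte = set()
    for ra in structure.residues:
        side_a = ra.chain in chains_a
        for rb in structure.residues:
            if (rb.chain in chains_a) == side_a:
                continue
            d = np.linalg.norm(
                structure.coords[ra.start:ra.stop, None, :]
                - structure.coords[None, rb.start:rb.stop, :],
                axis=2,
            ).min()
            if d <= D:
                inte.add(ra.key)
    return inte


class TestInterfaceResidues:
    def test_zero_distance_empty(self):
        part = interface_residues(_two_chain_toy(), ["A"], 0.0)
        assert part.inte == frozenset()
        assert len(part.non_inte) == 6

    def test_large_distance_all(self):
        part = interface_residues(_two_chain_toy(), ["A"], 100.0)
        assert part.non_inte == frozenset()
        assert len(part.inte) == 6

    def test_single_contact_pair_at_d5(self):
        s = _two_chain_toy()
        part = interface_residues(s, ["A"], 5.0)
        assert part.inte == frozenset({("A", 1), ("B", 1)})
        assert part.inte == frozenset(_brute_interface(s, ["A"], 5.0))

    def test_matches_brute_force_on_grid(self):
        s = build_structure(
            ScenarioSpec(seed=0, geometry="two_blob", atoms_per_blob=8,
                         blob_radius=2.5, gap=1.0)
        )
        for D in (0.0, 2.0, 4.0, 6.0, 9.0):
            part = interface_residues(s, ["A"], D)
            assert part.inte == frozenset(_brute_interface(s, ["A"], D))

    def test_monotone_in_d(self):
        s = _two_chain_toy()
        prev = frozenset()
        for D in (0, 3, 5, 7, 9, 20):
            part = interface_residues(s, ["A"], D)
            assert prev <= part.inte
            prev = part.inte

    def test_empty_side_error(self):
        with pytest.raises(ValueError, match="empty"):
            interface_residues(_two_chain_toy(), ["A", "B"], 5.0)


class TestRegionalGamma:
    def test_eq3_identity_framewise(self, null_system):
        structure, traj, _ = null_system
        per = gamma_per_residue(structure, traj)
        g = gamma_global(structure, traj)
        keys = list(per)
        part = RegionPartition(
            D=5.0, inte=frozenset(keys[:4]), non_inte=frozenset(keys[4:]),
            chains_a=frozenset("A"),
        )
        g_inte, g_non = regional_gamma(per, part)
        np.testing.assert_allclose(g_inte.series + g_non.series, g.series,
                                   atol=1e-10)

    def test_empty_noninte_degenerate(self, null_system):
        structure, traj, _ = null_system
        per = gamma_per_residue(structure, traj)
        g = gamma_global(structure, traj)
        part = RegionPartition(
            D=99.0, inte=frozenset(per), non_inte=frozenset(),
            chains_a=frozenset("A"),
        )
        g_inte, g_non = regional_gamma(per, part)
        assert g_inte.mean == pytest.approx(g.mean, abs=1e-10)
        assert g_non.mean == 0.0

    def test_missing_residue_error(self, null_system):
        structure, traj, _ = null_system
        per = gamma_per_residue(structure, traj)
        part = RegionPartition(
            D=5.0, inte=frozenset({("Z", 99)}), non_inte=frozenset(per),
            chains_a=frozenset("A"),
        )
        with pytest.raises(KeyError, match="Z"):
            regional_gamma(per, part)


def _est(mean, se):
    return GammaEstimate(mean=mean, se=se, series=np.full(8, mean),
                         cutoff=5.0, scope="global")


class TestDeltaGamma:
    def test_global_closure_antibody_lysozyme(self):
        # published per-state coefficients for the D1.3 system
        dg = delta_gamma(_est(-20.6, 1.5), _est(-11.1, 0.4), _est(-5.2, 0.8))
        assert dg.value == pytest.approx(-4.3, abs=1e-12)
        assert dg.se == pytest.approx(np.sqrt(1.5**2 + 0.4**2 + 0.8**2), abs=1e-12)
        assert round(dg.se, 1) == 1.7

    def test_interface_regional_closure(self):
        dg13 = delta_gamma(_est(-6.7, 0.5), _est(-1.9, 0.2), _est(-1.8, 0.2))
        assert dg13.value == pytest.approx(-3.0, abs=1e-12)
        assert round(dg13.se, 1) == 0.6
        dg44 = delta_gamma(_est(-2.3, 0.6), _est(-2.1, 0.4), _est(-2.2, 0.4))
        assert dg44.value == pytest.approx(2.0, abs=1e-12)
        assert round(dg44.se, 1) == 0.8

    def test_null_case(self):
        dg = delta_gamma(_est(0, 0), _est(0, 0), _est(0, 0))
        assert dg.value == 0.0
        assert dg.se == 0.0


def _small_complex(seed, patch=None):
    return ScenarioSpec(
        seed=seed, geometry="two_blob", atoms_per_blob=10, blob_radius=3.0,
        gap=12.0, box=(44.0, 44.0, 44.0), n_water=400, n_cosolvent=44,
        n_frames=120, patch=patch,
    )


class TestDetermineInterfaceDistance:
    def test_null_generator_gives_smallest_grid_value(self):
        # blobs far apart: association changes nothing, every D passes
        spec = _small_complex(seed=5)
        s, t, _ = generate_system(spec, ground_truth=False)
        sa, ta, _ = generate_system(spec.free_spec("A"), ground_truth=False)
        sb, tb, _ = generate_system(spec.free_spec("B"), ground_truth=False)
        dstar, scan = determine_interface_distance(
            SolvationSystem(s, t), SolvationSystem(sa, ta), SolvationSystem(sb, tb),
            ["A"], d_grid=range(3, 9), k=1.0,
        )
        assert dstar == 3.0
        assert scan["pass"].all()

    def test_error_carries_scan(self):
        spec = _small_complex(seed=5)
        s, t, _ = generate_system(spec, ground_truth=False)
        sa, ta, _ = generate_system(spec.free_spec("A"), ground_truth=False)
        sb, tb, _ = generate_system(spec.free_spec("B"), ground_truth=False)
        with pytest.raises(InterfaceScanError) as err:
            determine_interface_distance(
                SolvationSystem(s, t), SolvationSystem(sa, ta),
                SolvationSystem(sb, tb), ["A"], d_grid=range(3, 9), k=0.0,
            )
        assert len(err.value.scan) == 6


class TestResidueDeltaMap:
    def test_patch_residue_significant_positive(self):
        # cosolvent-binding patch on one residue of blob A, complex only
        patch = Patch(chain="A", residue=2, radius=3.5, factor_cosolvent=8.0)
        spec = _small_complex(seed=21, patch=patch)
        s, t, _ = generate_system(spec, ground_truth=False)
        sa, ta, _ = generate_system(spec.free_spec("A"), ground_truth=False)
        sb, tb, _ = generate_system(spec.free_spec("B"), ground_truth=False)
        mapping = build_residue_mapping(s, sa, sb, ["A"])
        dmap = residue_delta_map(
            gamma_per_residue(s, t), gamma_per_residue(sa, ta),
            gamma_per_residue(sb, tb), mapping, k=2.0,
        )
        assert dmap[("A", 2)].significant
        assert dmap[("A", 2)].value > 0
        # untouched chain-B residues stay within 2 SE of zero
        insignificant_b = [k for k in dmap if k[0] == "B" and not dmap[k].significant]
        assert len(insignificant_b) >= 8

    def test_null_mostly_insignificant(self):
        spec = _small_complex(seed=33)
        s, t, _ = generate_system(spec, ground_truth=False)
        sa, ta, _ = generate_system(spec.free_spec("A"), ground_truth=False)
        sb, tb, _ = generate_system(spec.free_spec("B"), ground_truth=False)
        mapping = build_residue_mapping(s, sa, sb, ["A"])
        dmap = residue_delta_map(
            gamma_per_residue(s, t), gamma_per_residue(sa, ta),
            gamma_per_residue(sb, tb), mapping, k=2.0,
        )
        n_sig = sum(d.significant for d in dmap.values())
        assert n_sig <= max(2, int(0.15 * len(dmap)))

    def test_unmapped_residue_error(self, null_system):
        structure, traj, _ = null_system
        per = gamma_per_residue(structure, traj)
        with pytest.raises(KeyError):
            residue_delta_map(per, per, per, mapping={}, k=2.0)


class TestResidueMapping:
    def test_identity_mapping_by_chain_number_name(self):
        spec = _small_complex(seed=1)
        s = build_structure(spec)
        sa = build_structure(spec.free_spec("A"))
        sb = build_structure(spec.free_spec("B"))
        mapping = build_residue_mapping(s, sa, sb, ["A"])
        assert all(mapping[k][1] == k for k in mapping)
        sides = {mapping[k][0] for k in mapping if k[0] == "A"}
        assert sides == {"A"}

    def test_missing_counterpart_error(self):
        spec = _small_complex(seed=1)
        s = build_structure(spec)
        sa = build_structure(spec.free_spec("A"))
        with pytest.raises(KeyError, match="no counterpart"):
            build_residue_mapping(s, sa, sa, ["A"])
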