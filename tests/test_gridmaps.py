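"""Occupancy grids, preference classification, hydration sites, OpenDX I/O."""

import numpy as np
import pytest

from prefint.gridmaps import (
    COSOLVENT_PREFERRED,
    NEUTRAL,
    UNDERSAMPLED,
    WATER_PREFERRED,
    ConcentrationGrid,
    accumulate_grid,
    classify_preferential,
    find_hydration_sites,
    read_dx,
    write_dx,
)
from prefint.synthetic import ScenarioSpec, generate_system

from conftest import single_atom_solute, trajectory_from_points


def _point_trajectory(water_points_per_frame, box=None):
    w = np.asarray(water_points_per_frame, dtype=float)
    x = np.zeros((w.shape[0], 1, 3)) + (
        np.array(box) / 2 + 11.0 if box is not None else 25.0
    )
    return trajectory_from_points(w, x[:, None, :].reshape(w.shape[0], 1, 3), box=box)


class TestAccumulateGrid:
    def test_single_atom_single_voxel(self):
        s = single_atom_solute()
        t = _point_trajectory(np.array([[[3.14, -2.0, 1.0]]]))
        grid = accumulate_grid(s, t, spacing=1.0, padding=12.0)
        assert grid.counts["water"].sum() == 1
        ijk = np.unravel_index(np.argmax(grid.counts["water"]), grid.shape)
        lo = grid.origin + np.array(ijk) * grid.spacing
        assert np.all(lo <= [3.14, -2.0, 1.0])
        assert np.all(np.array([3.14, -2.0, 1.0]) < lo + grid.spacing)

    def test_out_of_bounds_atoms_ignored(self):
        s = single_atom_solute()
        t = _point_trajectory(np.array([[[500.0, 0.0, 0.0]]]))
        grid = accumulate_grid(s, t, spacing=1.0, padding=10.0)
        assert grid.counts["water"].sum() == 0

    def test_occupancy_conservation(self, null_system):
        structure, traj, _ = null_system
        sub = type(traj)(
            water=traj.water[:30], cosolvent=traj.cosolvent[:30],
            boxes=traj.boxes[:30],
        )
        # grid covers the whole periodic box: every deposit is in bounds
        grid = accumulate_grid(structure, sub, spacing=1.0, padding=16.0)
        assert grid.counts["water"].sum() == 30 * sub.n_water
        assert grid.counts["cosolvent"].sum() == 30 * sub.n_cosolvent

    def test_bulk_region_requires_padding(self):
        s = single_atom_solute()
        t = _point_trajectory(np.array([[[2.0, 0.0, 0.0]]]))
        with pytest.raises(ValueError, match="padding"):
            accumulate_grid(s, t, spacing=1.0, padding=2.0)

    def test_bulk_density_poisson_consistency(self, null_system):
        structure, traj, _ = null_system
        grid = accumulate_grid(structure, traj, spacing=2.0, padding=16.0)
        rho = grid.bulk_density["water"]
        # uniform solvent: voxel counts ~ Poisson(rho * V * F) in the bulk
        expected = rho * grid.voxel_volume() * grid.n_frames
        centers = grid.voxel_centers().reshape(-1, 3)
        from prefint.shells import SoluteSurface
        surf = SoluteSurface(structure, box=traj.boxes[0])
        inside_box = np.all((centers >= 1.0) & (centers < 31.0), axis=1)
        bulk = (surf.surface_distance(centers) > grid.bulk_margin) & inside_box
        counts = grid.counts["water"].reshape(-1)[bulk]
        z = (counts - expected) / np.sqrt(expected)
        assert np.mean(np.abs(z) <= 3) >= 0.99


class TestClassifyPreferential:
    def _uniform_grid(self, c_w, c_x, rho_w=0.03, rho_x=0.003):
        shape = (2, 2, 2)
        return ConcentrationGrid(
            origin=np.zeros(3), spacing=1.0, shape=shape,
            counts={
                "water": np.full(shape, c_w, dtype=np.int64),
                "cosolvent": np.full(shape, c_x, dtype=np.int64),
            },
            n_frames=100, bulk_density={"water": rho_w, "cosolvent": rho_x},
            bulk_margin=8.0,
        )

    def test_bulk_ratio_is_neutral(self):
        grid = self._uniform_grid(c_w=1000, c_x=100)  # exactly bulk ratio
        cls = classify_preferential(grid, fold=2.0, min_occupancy=20)
        assert np.all(cls == NEUTRAL)

    def test_zero_occupancy_undersampled(self):
        grid = self._uniform_grid(c_w=0, c_x=0)
        cls = classify_preferential(grid)
        assert np.all(cls == UNDERSAMPLED)

    def test_enriched_and_depleted_voxels(self):
        grid = self._uniform_grid(c_w=1000, c_x=300)  # 3x bulk ratio
        assert np.all(classify_preferential(grid, fold=2.0) == COSOLVENT_PREFERRED)
        grid = self._uniform_grid(c_w=1000, c_x=30)   # 0.3x bulk ratio
        assert np.all(classify_preferential(grid, fold=2.0) == WATER_PREFERRED)

    def test_rescaling_invariance(self):
        grid = self._uniform_grid(c_w=500, c_x=150)
        ref = classify_preferential(grid, fold=2.0, min_occupancy=20)
        scaled = self._uniform_grid(c_w=2000, c_x=600)
        np.testing.assert_array_equal(
            classify_preferential(scaled, fold=2.0, min_occupancy=20), ref
        )

    def test_generator_shell_enrichment_recovered(self):
        spec = ScenarioSpec(
            seed=4, geometry="sphere", atoms_per_blob=12, blob_radius=3.0,
            box=(34.0, 34.0, 34.0), n_water=400, n_cosolvent=120,
            shell_factor_cosolvent=4.0, n_frames=400,
        )
        s, t, _ = generate_system(spec, ground_truth=False)
        grid = accumulate_grid(s, t, spacing=2.0, padding=12.0)
        cls = classify_preferential(grid, fold=2.0, min_occupancy=20)
        from prefint.shells import SoluteSurface
        surf = SoluteSurface(s, box=t.boxes[0])
        centers = grid.voxel_centers().reshape(-1, 3)
        sd = surf.surface_distance(centers)
        shell = (sd > 0.5) & (sd < spec.shell_width - 0.5)
        shell_cls = cls.reshape(-1)[shell]
        sampled = shell_cls != UNDERSAMPLED
        assert np.mean(shell_cls[sampled] == COSOLVENT_PREFERRED) > 0.5
        inside_box = np.all((centers >= 2.0) & (centers < 32.0), axis=1)
        bulk = (sd > grid.bulk_margin) & inside_box
        bulk_cls = cls.reshape(-1)[bulk]
        sampled_bulk = bulk_cls != UNDERSAMPLED
        assert np.mean(bulk_cls[sampled_bulk] == NEUTRAL) > 0.9


class TestHydrationSites:
    def test_fixed_water_gives_single_full_occupancy_site(self):
        s = single_atom_solute()
        pos = np.tile(np.array([[[4.0, 0.0, 0.0]]]), (50, 1, 1))
        t = _point_trajectory(pos)
        grid = accumulate_grid(s, t, spacing=1.0, padding=12.0)
        sites = find_hydration_sites(grid, t, site_radius=1.0)
        assert len(sites) == 1
        assert sites[0].occupancy == 1.0
        assert np.linalg.norm(sites[0].center - [4.0, 0.0, 0.0]) < 1.0

    def test_uniform_solvent_yields_no_sites(self, null_system):
        structure, traj, _ = null_system
        grid = accumulate_grid(structure, traj, spacing=1.0, padding=12.0)
        sites = find_hydration_sites(
            grid, traj, site_radius=1.0, min_occupancy_fraction=0.5
        )
        assert sites == []

    def test_two_tethered_waters_recovered(self):
        s = single_atom_solute()
        rng = np.random.default_rng(0)
        a = np.array([4.0, 0.0, 0.0])
        b = np.array([4.0, 6.0, 0.0])
        frames = []
        for _ in range(80):
            frames.append([a + rng.normal(0, 0.15, 3), b + rng.normal(0, 0.15, 3)])
        t = _point_trajectory(np.array(frames))
        grid = accumulate_grid(s, t, spacing=1.0, padding=12.0)
        sites = find_hydration_sites(grid, t, site_radius=1.0)
        assert len(sites) == 2
        found = sorted(np.round(st.center[1]) for st in sites)
        assert found == [0.0, 6.0]

    def test_translation_equivariance(self):
        shift = np.array([5.0, -3.0, 2.0])
        s1 = single_atom_solute()
        pos = np.tile(np.array([[[4.0, 0.0, 0.0]]]), (30, 1, 1))
        t1 = _point_trajectory(pos)
        g1 = accumulate_grid(s1, t1, spacing=1.0, padding=12.0)
        sites1 = find_hydration_sites(g1, t1, site_radius=1.0)
        s2 = single_atom_solute()
        s2.coords = s2.coords + shift
        t2 = _point_trajectory(pos + shift)
        g2 = accumulate_grid(s2, t2, spacing=1.0, padding=12.0)
        sites2 = find_hydration_sites(g2, t2, site_radius=1.0)
        np.testing.assert_allclose(sites2[0].center, sites1[0].center + shift)


class TestOpenDX:
    def test_roundtrip_small_grid(self, tmp_path):
        values = np.arange(8.0).reshape(2, 2, 2) / 3.0
        path = tmp_path / "field.dx"
        write_dx(values, origin=[1.0, 2.0, 3.0], spacing=0.5, path=path)
        back, origin, spacing = read_dx(path)
        np.testing.assert_allclose(back, values, rtol=1e-5)
        np.testing.assert_allclose(origin, [1.0, 2.0, 3.0])
        assert spacing == 0.5

    def test_classification_codes_roundtrip(self, tmp_path):
        codes = np.array([[[-1, 0], [1, 2]], [[2, 1], [0, -1]]], dtype=float)
        path = tmp_path / "classes.dx"
        write_dx(codes, origin=[0, 0, 0], spacing=1.0, path=path)
        back, _, _ = read_dx(path)
        np.testing.assert_array_equal(back, codes)

    def test_empty_grid_valid_file(self, tmp_path):
        path = tmp_path / "zeros.dx"
        write_dx(np.zeros((3, 3, 3)), origin=[0, 0, 0], spacing=1.0, path=path)
        back, _, _ = read_dx(path)
        assert back.shape == (3, 3, 3)
        assert np.all(back == 0)

    def test_z_fastest_ordering(self, tmp_path):
        # the flattened stream must vary z fastest (viewer convention)
        values = np.zeros((2, 2, 2))
        values[1, 0, 0] = 7.0
        path = tmp_path / "order.dx"
        write_dx(values, origin=[0, 0, 0], spacing=1.0, path=path)
        data = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if parts and all(p.replace(".", "").replace("-", "").isdigit()
                             for p in parts) and len(parts) <= 3:
                data.extend(float(p) for p in parts)
        assert data[4] == 7.0  # index x=1,y=0,z=0 -> position 4 of 8
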