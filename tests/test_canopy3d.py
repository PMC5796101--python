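"""Plant generator: allometry, phyllotaxis, mesh consistency, I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mangoray.canopy3d import (
    ALLOMETRY_COEFFS,
    IRWIN_DIVERGENCE_ANGLES_DEG,
    AllometryDomainError,
    LeafRecord,
    PlantConfig,
    build_plant,
    canopy_z_extent,
    leaf_area_from_dimensions,
    phyllotaxis_azimuths,
    read_leaf_table,
    read_obj,
    write_leaf_table,
    write_obj,
    write_ply,
)


class TestAllometry:
    @pytest.mark.parametrize("L, W, expected", [
        (20.0, 5.0, 71.047),
        (10.0, 4.0, 33.405),
        (25.0, 6.0, 103.218),
    ])
    def test_printed_formula_values(self, L, W, expected):
        assert leaf_area_from_dimensions(L, W) == pytest.approx(expected, abs=1e-9)

    def test_small_leaves_rejected_not_clamped(self):
        with pytest.raises(AllometryDomainError):
            leaf_area_from_dimensions(1.0, 0.5)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            leaf_area_from_dimensions(0.0, 5.0)

    @given(st.floats(10, 30), st.floats(3, 8))
    def test_matches_polynomial(self, L, W):
        c0, c1, c2, c3 = ALLOMETRY_COEFFS
        assert leaf_area_from_dimensions(L, W) == pytest.approx(
            c0 + c1 * W + c2 * L ** 2 + c3 * W ** 2)


class TestPhyllotaxis:
    def test_measured_angles_average_near_golden(self):
        assert np.mean(IRWIN_DIVERGENCE_ANGLES_DEG) == pytest.approx(137.6, abs=0.05)

    def test_quarter_turns_close_the_circle(self):
        az = phyllotaxis_azimuths([90, 90, 90, 90], start_azimuth=0.0)
        assert np.allclose(az, [0, 90, 180, 270, 0])

    def test_output_one_longer_than_input(self):
        az = phyllotaxis_azimuths(IRWIN_DIVERGENCE_ANGLES_DEG, 10.0)
        assert len(az) == len(IRWIN_DIVERGENCE_ANGLES_DEG) + 1
        assert az[0] == 10.0

    def test_golden_spiral_avoids_azimuthal_overlap(self):
        # brute-force pairwise separation for a near-golden-angle spiral
        az = phyllotaxis_azimuths([137.6] * 13, 0.0)
        assert len(az) == 14
        for i in range(len(az)):
            for j in range(i + 1, len(az)):
                d = abs(az[i] - az[j]) % 360.0
                assert min(d, 360.0 - d) > 5.0

    @given(st.lists(st.floats(0, 359), min_size=1, max_size=20),
           st.floats(0, 359))
    def test_consecutive_differences_reproduce_angles(self, angles, start):
        az = phyllotaxis_azimuths(angles, start)
        for k, a in enumerate(angles):
            d = (az[k + 1] - az[k]) % 360.0
            assert d == pytest.approx(a % 360.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phyllotaxis_azimuths([], 0.0)


class TestBuildPlant:
    def test_total_area_matches_reference_target(self, default_plant):
        mesh, recs = default_plant
        total = sum(r.allometric_area for r in recs)
        # the study plant's total one-sided area, within 0.5%
        assert total == pytest.approx(4194.84, rel=5e-3)

    def test_mesh_area_matches_allometric_area(self, default_plant):
        mesh, recs = default_plant
        areas = mesh.triangle_areas()
        for r in recs:
            mesh_area = areas[mesh.element_id == r.leaf_id].sum() * 1e4
            assert mesh_area == pytest.approx(r.allometric_area, rel=1e-2)

    @pytest.mark.parametrize("seed", range(25))
    def test_mesh_record_consistency_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        cfg = PlantConfig(
            n_leaves=int(rng.integers(4, 40)),
            leaf_length_range=tuple(np.sort(rng.uniform(15, 28, 2))),
            leaf_width_range=tuple(np.sort(rng.uniform(4, 7, 2))),
            inclination_range=tuple(np.sort(rng.uniform(-40, 50, 2))),
            target_total_leaf_area=float(rng.uniform(2000, 6000)),
            rng_seed=seed,
        )
        mesh, recs = cfg and build_plant(cfg)
        areas = mesh.triangle_areas()
        for r in recs:
            mesh_area = areas[mesh.element_id == r.leaf_id].sum() * 1e4
            assert mesh_area == pytest.approx(r.allometric_area, rel=1e-2)
        total = sum(r.allometric_area for r in recs)
        assert total == pytest.approx(cfg.target_total_leaf_area, rel=5e-3)

    def test_branch_azimuth_sequence_follows_divergence(self):
        angles = [137.6, 120.0, 150.0, 100.0, 137.6]
        cfg = PlantConfig(n_leaves=24, divergence_angles=list(angles))
        mesh, recs = build_plant(cfg)
        by_branch = {}
        for r in recs:
            by_branch.setdefault(r.branch_id, []).append(r)
        for branch in by_branch.values():
            for k in range(len(branch) - 1):
                d = (branch[k + 1].azimuth - branch[k].azimuth) % 360.0
                expected = angles[k % len(angles)] % 360.0
                assert d == pytest.approx(expected, abs=1e-9)

    def test_rescaling_preserves_area_fractions(self):
        base = PlantConfig(target_total_leaf_area=None, rng_seed=3)
        scaled = PlantConfig(target_total_leaf_area=3000.0, rng_seed=3)
        _, r0 = build_plant(base)
        _, r1 = build_plant(scaled)
        a0 = np.array([r.allometric_area for r in r0])
        a1 = np.array([r.allometric_area for r in r1])
        f0 = a0 / a0.sum()
        f1 = a1 / a1.sum()
        assert np.allclose(f0, f1, rtol=1e-6)

    def test_leaf_centroids_inside_chamber_footprint(self, default_plant):
        mesh, recs = default_plant
        for r in recs:
            c = mesh.element_centroid(r.leaf_id)
            assert abs(c[0]) <= 0.5 and abs(c[1]) <= 0.5

    def test_single_leaf_plant(self):
        mesh, recs = build_plant(PlantConfig(n_leaves=1))
        assert len(recs) == 1
        kinds = set(mesh.element_kind)
        assert kinds == {"leaf", "stem", "pot"}
        assert (mesh.element_kind == "leaf").sum() >= 8  # >= 8 triangles

    def test_determinism_bitwise(self):
        cfg = PlantConfig(rng_seed=11)
        m1, _ = build_plant(cfg)
        m2, _ = build_plant(cfg)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.triangles, m2.triangles)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            build_plant(PlantConfig(n_leaves=0))
        with pytest.raises(ValueError):
            build_plant(PlantConfig(leaf_length_range=(26.0, 18.0)))
        with pytest.raises(AllometryDomainError):
            build_plant(PlantConfig(leaf_length_range=(0.5, 1.0),
                                    leaf_width_range=(0.2, 0.4),
                                    target_total_leaf_area=None))


class TestIO:
    def test_obj_round_trip(self, default_plant, tmp_path):
        mesh, _ = default_plant
        path = tmp_path / "plant.obj"
        write_obj(mesh, path)
        back = read_obj(path)
        assert back.n_triangles == mesh.n_triangles
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        assert np.array_equal(back.element_id, mesh.element_id)
        assert list(back.element_kind) == list(mesh.element_kind)

    def test_ply_export_loads_in_trimesh(self, default_plant, tmp_path):
        import trimesh

        mesh, _ = default_plant
        path = tmp_path / "plant.ply"
        write_ply(mesh, path)
        tm = trimesh.load(str(path), process=False)
        assert len(tm.faces) == mesh.n_triangles

    def test_leaf_table_round_trip(self, default_plant, tmp_path):
        _, recs = default_plant
        path = tmp_path / "leaves.csv"
        write_leaf_table(recs, path)
        back = read_leaf_table(path)
        assert len(back) == len(recs)
        assert back[0].leaf_id == recs[0].leaf_id
        assert back[5].allometric_area == pytest.approx(
            recs[5].allometric_area, rel=1e-6)

    def test_leaf_record_validation(self):
        with pytest.raises(ValueError):
            LeafRecord(0, 20.0, 5.0, 3.0, -1.0, 10.0, 0.0, 1.0, 0)
        with pytest.raises(ValueError):
            LeafRecord(0, 20.0, 5.0, 3.0, 70.0, 361.0, 0.0, 1.0, 0)
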