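"""Monte Carlo transport: intersection exactness, analytic radiative oracles,
energy-ledger closure, convergence and linearity."""

import math

import numpy as np
import pytest

from mangoray.canopy3d import (TriangleMesh, concat_meshes, make_quad,
                               random_flat_leaf_field)
from mangoray.lightenv import BeamSource, LampSource, SceneIllumination, SkySource
from mangoray.raytracer import (
    BLACK,
    DEFAULT_LEAF_OPTICS,
    IrradianceMap,
    MaterialError,
    MeshAccel,
    OpticalMaterial,
    TraceConfig,
    calibrate_lamp,
    leaf_ppfd_table,
    nearest_hit,
    trace,
)


def _single_leaf(tilt_deg=0.0, z=0.5, size=0.1):
    leaf = make_quad([0, 0, z], size, "z", element=0, kind="leaf")
    if tilt_deg:
        a = math.radians(tilt_deg)
        R = np.array([[1, 0, 0],
                      [0, math.cos(a), -math.sin(a)],
                      [0, math.sin(a), math.cos(a)]])
        c = np.array([0, 0, z])
        verts = (leaf.vertices - c) @ R.T + c
        leaf = TriangleMesh(verts, leaf.triangles, leaf.element_id,
                            leaf.element_kind)
    return leaf


def _ledger_gap(m: IrradianceMap) -> float:
    led = m.ledger
    return abs(led["emitted"] - led["absorbed"] - led["escaped"]
               - led["truncated"])


class TestNearestHit:
    def test_hit_through_centroid_exact_distance(self):
        verts = np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 1.0]])
        mesh = TriangleMesh(verts, np.array([[0, 1, 2]], np.int32),
                            np.array([0], np.int32), np.array(["leaf"]))
        centroid = verts.mean(axis=0)
        origin = centroid + np.array([0, 0, 2.0])
        hit = nearest_hit(origin, np.array([0, 0, -1.0]), mesh)
        assert hit is not None
        tri, dist, (u, v) = hit
        assert tri == 0
        assert dist == pytest.approx(2.0, rel=1e-12)
        assert u == pytest.approx(1 / 3, rel=1e-9)
        assert v == pytest.approx(1 / 3, rel=1e-9)

    def test_coplanar_parallel_ray_misses(self):
        verts = np.array([[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0]])
        mesh = TriangleMesh(verts, np.array([[0, 1, 2]], np.int32),
                            np.array([0], np.int32), np.array(["leaf"]))
        hit = nearest_hit(np.array([-1.0, 0.25, 0.0]),
                          np.array([1.0, 0.0, 0.0]), mesh)
        assert hit is None

    def test_unnormalized_direction_rejected(self):
        verts = np.array([[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0]])
        mesh = TriangleMesh(verts, np.array([[0, 1, 2]], np.int32),
                            np.array([0], np.int32), np.array(["leaf"]))
        with pytest.raises(ValueError):
            nearest_hit(np.zeros(3), np.array([0, 0, -2.0]), mesh)

    def test_bvh_identical_to_brute_force(self):
        rng = np.random.default_rng(0)
        # 500 random triangles in the unit cube
        v = rng.uniform(0, 1, (500, 3, 3))
        v[:, 1:] = v[:, :1] + 0.1 * (v[:, 1:] - v[:, :1])
        verts = v.reshape(-1, 3)
        tris = np.arange(1500, dtype=np.int32).reshape(-1, 3)
        mesh = TriangleMesh(verts, tris, np.zeros(500, np.int32),
                            np.array(["leaf"] * 500))
        accel = MeshAccel(mesh)
        for _ in range(1000):
            o = rng.uniform(-0.5, 1.5, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            fast = nearest_hit(o, d, mesh, accel)
            slow = nearest_hit(o, d, mesh, accel, brute_force=True)
            if slow is None:
                assert fast is None
            else:
                assert fast is not None
                assert fast[0] == slow[0]
                assert fast[1] == slow[1]  # bitwise-identical distance


class TestTraceOracles:
    def test_full_interception_horizontal_black_leaf(self, vertical_beam):
        m = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam,
                  TraceConfig(n_rays=1_000_000, rng_seed=42))
        p = m.ppfd(0)
        assert p == pytest.approx(1000.0, rel=5e-3)
        assert abs(p - 1000.0) < 3.5 * max(m.ppfd_se(0), 1e-9)

    def test_cosine_law_tilted_leaf(self, vertical_beam):
        m = trace(_single_leaf(tilt_deg=60.0), {"leaf": BLACK}, vertical_beam,
                  TraceConfig(n_rays=1_000_000, rng_seed=42))
        assert m.ppfd(0) == pytest.approx(500.0, rel=5e-3)

    def test_beer_lambert_gap_fraction(self, vertical_beam):
        # LAI-1 random horizontal black canopy: mean floor gap -> e^-1
        floor = make_quad([0.5, 0.5, 0.0], 0.9, "z", element=1000, kind="floor")
        gaps = []
        for s in range(4):
            field, _ = random_flat_leaf_field(500, 1.0, rng_seed=50 + s,
                                              z_range=(0.1, 0.9))
            scene = concat_meshes(field, floor)
            m = trace(scene, {"leaf": BLACK, "floor": BLACK}, vertical_beam,
                      TraceConfig(n_rays=150_000, rng_seed=s))
            gaps.append(m.incident_flux[m._index[1000]] / (1000.0 * 0.81))
        # 4 configurations: configuration-to-configuration scatter ~0.01
        assert np.mean(gaps) == pytest.approx(math.exp(-1), abs=0.02)

    def test_zero_flux_gives_zero_map(self):
        ill = SceneIllumination(sky=SkySource(horizontal_ppfd=0.0))
        m = trace(_single_leaf(), {"leaf": BLACK}, ill,
                  TraceConfig(n_rays=1000, rng_seed=0))
        assert m.incident_flux.sum() == 0.0
        assert m.ledger["emitted"] == 0.0


class TestLedgerAndInvariants:
    @pytest.mark.parametrize("mats", [
        {"leaf": BLACK, "floor": BLACK},
        {"leaf": DEFAULT_LEAF_OPTICS, "floor": OpticalMaterial(0.3, 0.0)},
        {"leaf": OpticalMaterial(0.45, 0.45), "floor": OpticalMaterial(0.9, 0.0)},
    ])
    def test_energy_ledger_closes(self, vertical_beam, mats):
        field, _ = random_flat_leaf_field(100, 0.5, rng_seed=1)
        floor = make_quad([0.5, 0.5, 0.0], 1.0, "z", element=999, kind="floor")
        scene = concat_meshes(field, floor)
        m = trace(scene, mats, vertical_beam,
                  TraceConfig(n_rays=100_000, rng_seed=2, max_impacts=10))
        assert _ledger_gap(m) < 1e-9 * m.ledger["emitted"]
        assert m.ledger["truncated"] >= 0.0

    def test_black_leaves_insensitive_to_max_impacts(self, vertical_beam):
        field, _ = random_flat_leaf_field(50, 0.3, rng_seed=4)
        m1 = trace(field, {"leaf": BLACK}, vertical_beam,
                   TraceConfig(n_rays=50_000, rng_seed=7, max_impacts=1))
        m2 = trace(field, {"leaf": BLACK}, vertical_beam,
                   TraceConfig(n_rays=50_000, rng_seed=7, max_impacts=10))
        assert np.array_equal(m1.incident_flux, m2.incident_flux)
        assert m1.ledger == m2.ledger

    def test_se_scales_inverse_sqrt_n(self, vertical_beam):
        ses = []
        ns = [10_000, 100_000, 1_000_000]
        for n in ns:
            m = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam,
                      TraceConfig(n_rays=n, rng_seed=5))
            ses.append(m.ppfd_se(0))
        for k in range(2):
            ratio = ses[k] / ses[k + 1]
            assert ratio == pytest.approx(math.sqrt(10), rel=0.2)

    def test_rigid_rotation_leaves_ppfd_unchanged(self):
        field, _ = random_flat_leaf_field(30, 0.3, rng_seed=9)
        d = np.array([0.3, -0.2, -1.0])
        d /= np.linalg.norm(d)
        cfg = TraceConfig(n_rays=400_000, rng_seed=3)
        m0 = trace(field, {"leaf": BLACK},
                   SceneIllumination(beam=BeamSource(d, 1000.0)), cfg)
        ang = math.radians(73.0)
        R = np.array([[math.cos(ang), -math.sin(ang), 0],
                      [math.sin(ang), math.cos(ang), 0],
                      [0, 0, 1.0]])
        rot = TriangleMesh(field.vertices @ R.T, field.triangles,
                           field.element_id, field.element_kind)
        m1 = trace(rot, {"leaf": BLACK},
                   SceneIllumination(beam=BeamSource(R @ d, 1000.0)), cfg)
        for e in range(30):
            se = math.hypot(m0.ppfd_se(e), m1.ppfd_se(e))
            assert abs(m0.ppfd(e) - m1.ppfd(e)) < max(4.0 * se, 1e-9)

    def test_determinism_same_seed(self, vertical_beam):
        cfg = TraceConfig(n_rays=20_000, rng_seed=12)
        m1 = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam, cfg)
        m2 = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam, cfg)
        assert np.array_equal(m1.incident_flux, m2.incident_flux)

    def test_missing_material_is_an_error(self, vertical_beam):
        with pytest.raises(MaterialError):
            trace(_single_leaf(), {"floor": BLACK}, vertical_beam,
                  TraceConfig(n_rays=100, rng_seed=0))


class TestLampAndSensors:
    def _lamp_scene(self):
        sensor = make_quad([0, 0, 1.0], 0.05, "z", element=10, kind="sensor")
        lamp_geo = make_quad([0, 0, 2.55], 0.05, "z", element=11, kind="lamp")
        scene = concat_meshes(sensor, lamp_geo)
        ill = SceneIllumination(lamp=LampSource(
            center=np.array([0, 0, 2.5]), radius=0.05, total_flux=1000.0))
        mats = {"sensor": BLACK, "lamp": BLACK}
        return scene, ill, mats

    def test_point_source_far_field_inverse_square(self):
        # small Lambertian disc ~ point source: E = (flux/pi) * cos^3 / h^2
        # on-axis below the lamp, cos=1
        sensor = make_quad([0, 0, 0.0], 0.08, "z", element=0, kind="sensor")
        for h, elem in ((2.0, 0), (4.0, 0)):
            ill = SceneIllumination(lamp=LampSource(
                center=np.array([0, 0, h]), radius=0.004, total_flux=1000.0))
            m = trace(sensor, {"sensor": BLACK}, ill,
                      TraceConfig(n_rays=2_000_000, rng_seed=8))
            expected = 1000.0 / math.pi / h ** 2
            assert m.ppfd(0) == pytest.approx(expected, rel=0.05)

    def test_calibration_reaches_target(self):
        scene, ill, mats = self._lamp_scene()
        flux, cal = calibrate_lamp(scene, mats, ill, 10, 833.1,
                                   TraceConfig(n_rays=300_000, rng_seed=2))
        assert cal.ppfd(10) == pytest.approx(833.1, rel=1e-9)
        assert flux > 0

    def test_calibration_linearity(self):
        scene, ill, mats = self._lamp_scene()
        cfg = TraceConfig(n_rays=100_000, rng_seed=2)
        base = trace(scene, mats, ill, cfg)
        doubled = base.scaled(2.0)
        assert np.allclose(doubled.incident_flux, 2.0 * base.incident_flux)
        assert doubled.ledger["emitted"] == pytest.approx(
            2.0 * base.ledger["emitted"])

    def test_zero_target_gives_zero_flux(self):
        scene, ill, mats = self._lamp_scene()
        flux, cal = calibrate_lamp(scene, mats, ill, 10, 0.0,
                                   TraceConfig(n_rays=50_000, rng_seed=2))
        assert flux == 0.0
        assert cal.incident_flux.sum() == 0.0

    def test_unlit_sensor_cannot_calibrate(self):
        scene, ill, mats = self._lamp_scene()
        # sensor 10 is below an opaque lamp quad? use a shadowed sensor:
        blocked = concat_meshes(
            scene, make_quad([0, 0, 1.5], 0.5, "z", element=12, kind="floor"))
        mats = dict(mats, floor=BLACK)
        with pytest.raises(RuntimeError):
            calibrate_lamp(blocked, mats, ill, 10, 833.1,
                           TraceConfig(n_rays=50_000, rng_seed=2))


class TestLeafTable:
    def test_single_leaf_row(self, vertical_beam):
        m = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam,
                  TraceConfig(n_rays=100_000, rng_seed=1))

        class Rec:
            leaf_id = 0

        tab = leaf_ppfd_table(m, [Rec()])
        assert list(tab.columns) == ["leaf_id", "ppfd", "se"]
        assert len(tab) == 1
        assert tab.ppfd[0] == pytest.approx(1000.0, rel=0.02)

    def test_empty_leaf_list(self, vertical_beam):
        m = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam,
                  TraceConfig(n_rays=1000, rng_seed=1))
        tab = leaf_ppfd_table(m, [])
        assert len(tab) == 0

    def test_unknown_leaf_id_raises(self, vertical_beam):
        m = trace(_single_leaf(), {"leaf": BLACK}, vertical_beam,
                  TraceConfig(n_rays=1000, rng_seed=1))

        class Rec:
            leaf_id = 99

        with pytest.raises(KeyError):
            leaf_ppfd_table(m, [Rec()])

    def test_patch_grids_integrate_to_leaf_flux(self, vertical_beam):
        m = trace(_single_leaf(size=0.1), {"leaf": BLACK}, vertical_beam,
                  TraceConfig(n_rays=200_000, rng_seed=6), keep_patches=True)
        grid = m.patch_grids[0]
        total = grid.sum() * 0.005 ** 2
        assert total == pytest.approx(m.incident_flux[m._index[0]], rel=1e-9)
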