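"""Monte Carlo forward ray tracing of photon packets through a plant scene.

Photon packets are sampled from each source (collimated beam, diffuse sky,
Lambertian disc lamp), traced against the triangle mesh through a BVH, and at
every surface hit the packet's flux weight is tallied as *incident* light on
that element (both faces count — matching a quantum sensor laminated to the
leaf). The packet then scatters bi-Lambertianly (reflect with probability
rho, transmit with probability tau, absorb otherwise) with constant weight,
so the energy ledger — emitted = absorbed + escaped + truncated — closes
exactly on packet counts. Glazing-like materials may instead transmit
specularly (direction preserved).

Per-leaf mean PPFD, its Monte Carlo standard error, and per-leaf detector
grids at a configurable pitch (5 mm default) are reported, alongside the
full energy ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .canopy3d import TriangleMesh

__all__ = [
    "OpticalMaterial",
    "TraceConfig",
    "IrradianceMap",
    "MeshAccel",
    "nearest_hit",
    "disc_visibility",
    "trace",
    "leaf_ppfd_table",
    "calibrate_lamp",
    "DEFAULT_LEAF_OPTICS",
    "BLACK",
]

_EPS_HIT = 1e-9      # minimum hit distance / restart offset, m
_KIND_CODE = {"leaf": 0, "stem": 1, "pot": 2, "wall": 3, "floor": 4,
              "lamp": 5, "sensor": 6}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}


class MaterialError(KeyError):
    """An element kind in the scene has no optical material assigned."""


@dataclass(frozen=True)
class OpticalMaterial:
    """PAR-band bi-Lambertian optics of a surface.

    ``diffuse_transmission=False`` marks glazing-like materials whose
    transmitted rays keep their direction (clear polycarbonate / glass);
    leaves scatter diffusely on both sides.
    """

    reflectance: float
    transmittance: float
    diffuse_transmission: bool = True

    def __post_init__(self):
        if not (0.0 <= self.reflectance <= 1.0 and 0.0 <= self.transmittance <= 1.0):
            raise ValueError("rho and tau must lie in [0, 1]")
        if self.reflectance + self.transmittance > 1.0 + 1e-12:
            raise ValueError("rho + tau must not exceed 1")

    @property
    def absorptance(self) -> float:
        return 1.0 - self.reflectance - self.transmittance


#: Typical PAR optics of a thick evergreen leaf.
DEFAULT_LEAF_OPTICS = OpticalMaterial(0.10, 0.05)
BLACK = OpticalMaterial(0.0, 0.0)


@dataclass
class TraceConfig:
    n_rays: int = 1_000_000
    max_impacts: int = 10
    detector_pitch: float = 0.005   # m
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_rays < 1 or self.max_impacts < 1 or self.detector_pitch <= 0:
            raise ValueError("invalid TraceConfig")


@dataclass
class IrradianceMap:
    """Per-element interception tallies plus the energy ledger of one trace."""

    element_ids: np.ndarray        # (k,)
    element_kind: np.ndarray       # (k,) unicode
    element_area: np.ndarray       # (k,) m^2 one-sided
    incident_flux: np.ndarray      # (k,) umol s^-1
    incident_se: np.ndarray        # (k,) umol s^-1 MC standard error
    ledger: dict                   # emitted / absorbed_by_kind / escaped / truncated
    n_rays: int
    patch_grids: dict = field(default_factory=dict)  # element -> 2D PPFD array

    def __post_init__(self):
        self._index = {int(e): i for i, e in enumerate(self.element_ids)}

    def ppfd(self, element: int) -> float:
        """Mean incident PPFD of an element (flux / one-sided area)."""
        i = self._index[int(element)]
        return float(self.incident_flux[i] / self.element_area[i])

    def ppfd_se(self, element: int) -> float:
        i = self._index[int(element)]
        return float(self.incident_se[i] / self.element_area[i])

    def scaled(self, factor: float) -> "IrradianceMap":
        """Linearity of transport: rescale every tally by ``factor``."""
        led = dict(self.ledger)
        for key in ("emitted", "escaped", "truncated"):
            led[key] = led[key] * factor
        led["absorbed_by_kind"] = {k: v * factor
                                   for k, v in self.ledger["absorbed_by_kind"].items()}
        return IrradianceMap(
            element_ids=self.element_ids, element_kind=self.element_kind,
            element_area=self.element_area,
            incident_flux=self.incident_flux * factor,
            incident_se=self.incident_se * factor,
            ledger=led, n_rays=self.n_rays,
            patch_grids={k: v * factor for k, v in self.patch_grids.items()})


# ----------------------------------------------------------------------------
# BVH construction (python) and traversal kernels (numba)
# ----------------------------------------------------------------------------

class MeshAccel:
    """Flattened median-split BVH over a mesh's triangles."""

    def __init__(self, mesh: TriangleMesh, leaf_size: int = 4):
        self.mesh = mesh
        tv = mesh.vertices[mesh.triangles]          # (m, 3, 3)
        self.v0 = np.ascontiguousarray(tv[:, 0])
        self.e1 = np.ascontiguousarray(tv[:, 1] - tv[:, 0])
        self.e2 = np.ascontiguousarray(tv[:, 2] - tv[:, 0])
        lo = tv.min(axis=1)
        hi = tv.max(axis=1)
        cent = tv.mean(axis=1)

        m = len(tv)
        order = np.arange(m)
        boxes_min, boxes_max = [], []
        lefts, rights, starts, counts = [], [], [], []

        def build(idx):
            node = len(boxes_min)
            boxes_min.append(lo[idx].min(axis=0))
            boxes_max.append(hi[idx].max(axis=0))
            lefts.append(-1)
            rights.append(-1)
            starts.append(-1)
            counts.append(-1)
            if len(idx) <= leaf_size:
                starts[node] = len(self._order_acc)
                counts[node] = len(idx)
                self._order_acc.extend(idx.tolist())
                return node
            span = cent[idx].max(axis=0) - cent[idx].min(axis=0)
            axis = int(np.argmax(span))
            med = np.argsort(cent[idx, axis], kind="stable")
            half = len(idx) // 2
            li = idx[med[:half]]
            ri = idx[med[half:]]
            lefts[node] = build(li)
            rights[node] = build(ri)
            return node

        self._order_acc: list[int] = []
        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10000))
        build(order)
        sys.setrecursionlimit(old)
        self.node_min = np.asarray(boxes_min)
        self.node_max = np.asarray(boxes_max)
        self.node_left = np.asarray(lefts, np.int32)
        self.node_right = np.asarray(rights, np.int32)
        self.node_start = np.asarray(starts, np.int32)
        self.node_count = np.asarray(counts, np.int32)
        self.tri_order = np.asarray(self._order_acc, np.int32)
        del self._order_acc


@njit(cache=True, error_model="numpy")
def _tri_hit(ox, oy, oz, dx, dy, dz, v0, e1, e2, i):
    """Möller–Trumbore; returns t (np.inf on miss)."""
    e1x, e1y, e1z = e1[i, 0], e1[i, 1], e1[i, 2]
    e2x, e2y, e2z = e2[i, 0], e2[i, 1], e2[i, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if abs(det) < 1e-14:
        return np.inf
    inv = 1.0 / det
    tx = ox - v0[i, 0]
    ty = oy - v0[i, 1]
    tz = oz - v0[i, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < 0.0 or u > 1.0:
        return np.inf
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < 0.0 or u + v > 1.0:
        return np.inf
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= _EPS_HIT:
        return np.inf
    return t


@njit(cache=True, error_model="numpy")
def _hit_brute(ox, oy, oz, dx, dy, dz, v0, e1, e2):
    best_t = np.inf
    best_i = -1
    for i in range(v0.shape[0]):
        t = _tri_hit(ox, oy, oz, dx, dy, dz, v0, e1, e2, i)
        if t < best_t or (t == best_t and t < np.inf and i < best_i):
            best_t = t
            best_i = i
    return best_t, best_i


@njit(cache=True, error_model="numpy")
def _box_tmin(ox, oy, oz, ix, iy, iz, bmin, bmax, node):
    t0 = (bmin[node, 0] - ox) * ix
    t1 = (bmax[node, 0] - ox) * ix
    if t0 > t1:
        t0, t1 = t1, t0
    u0 = (bmin[node, 1] - oy) * iy
    u1 = (bmax[node, 1] - oy) * iy
    if u0 > u1:
        u0, u1 = u1, u0
    if u0 > t0:
        t0 = u0
    if u1 < t1:
        t1 = u1
    w0 = (bmin[node, 2] - oz) * iz
    w1 = (bmax[node, 2] - oz) * iz
    if w0 > w1:
        w0, w1 = w1, w0
    if w0 > t0:
        t0 = w0
    if w1 < t1:
        t1 = w1
    if t1 < t0 or t1 < 0.0:
        return np.inf
    return t0


@njit(cache=True, error_model="numpy")
def _hit_bvh(ox, oy, oz, dx, dy, dz, v0, e1, e2,
             bmin, bmax, left, right, start, count, order):
    ix = 1.0 / dx
    iy = 1.0 / dy
    iz = 1.0 / dz
    best_t = np.inf
    best_i = -1
    stack = np.empty(128, np.int32)
    sp = 0
    stack[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        tmin = _box_tmin(ox, oy, oz, ix, iy, iz, bmin, bmax, node)
        if tmin > best_t:
            continue
        if count[node] >= 0:
            for k in range(start[node], start[node] + count[node]):
                i = order[k]
                t = _tri_hit(ox, oy, oz, dx, dy, dz, v0, e1, e2, i)
                if t < best_t or (t == best_t and t < np.inf and i < best_i):
                    best_t = t
                    best_i = i
        else:
            stack[sp] = left[node]
            sp += 1
            stack[sp] = right[node]
            sp += 1
    return best_t, best_i


def nearest_hit(ray_origin, ray_direction, mesh, accel: MeshAccel | None = None,
                brute_force: bool = False):
    """Closest ray/mesh intersection beyond the epsilon offset.

    Returns ``(triangle_index, distance, (u, v))`` barycentric coordinates of
    the hit, or ``None``. The BVH-accelerated search uses the identical
    per-triangle arithmetic as the exhaustive loop, so results agree exactly.
    """
    o = np.asarray(ray_origin, float)
    d = np.asarray(ray_direction, float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("ray direction must be normalized")
    if accel is None:
        accel = MeshAccel(mesh)
    if brute_force:
        t, i = _hit_brute(o[0], o[1], o[2], d[0], d[1], d[2],
                          accel.v0, accel.e1, accel.e2)
    else:
        t, i = _hit_bvh(o[0], o[1], o[2], d[0], d[1], d[2],
                        accel.v0, accel.e1, accel.e2,
                        accel.node_min, accel.node_max, accel.node_left,
                        accel.node_right, accel.node_start, accel.node_count,
                        accel.tri_order)
    if i < 0:
        return None
    # recover barycentric coordinates
    tv0 = accel.v0[i]
    p = o + t * d
    r = p - tv0
    e1, e2 = accel.e1[i], accel.e2[i]
    a11 = e1 @ e1
    a12 = e1 @ e2
    a22 = e2 @ e2
    det = a11 * a22 - a12 * a12
    u = (a22 * (r @ e1) - a12 * (r @ e2)) / det
    v = (a11 * (r @ e2) - a12 * (r @ e1)) / det
    return int(i), float(t), (float(u), float(v))


# ----------------------------------------------------------------------------
# transport kernel
# ----------------------------------------------------------------------------

@njit(cache=True, error_model="numpy", inline="always")
def _cosine_dir(nx, ny, nz):
    """Cosine-weighted direction about normal n (assumed unit)."""
    r1 = np.random.random()
    r2 = np.random.random()
    phi = 2.0 * math.pi * r1
    st = math.sqrt(r2)
    ct = math.sqrt(1.0 - r2)
    # orthonormal basis around n
    if abs(nx) < 0.9:
        bx, by, bz = 0.0, nz, -ny
    else:
        bx, by, bz = -nz, 0.0, nx
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    bx /= nb
    by /= nb
    bz /= nb
    cx = ny * bz - nz * by
    cy = nz * bx - nx * bz
    cz = nx * by - ny * bx
    dx = st * math.cos(phi) * bx + st * math.sin(phi) * cx + ct * nx
    dy = st * math.cos(phi) * by + st * math.sin(phi) * cy + ct * ny
    dz = st * math.cos(phi) * bz + st * math.sin(phi) * cz + ct * nz
    return dx, dy, dz


@njit(cache=True, error_model="numpy")
def _trace_source(mode, n_rays, seed, max_impacts,
                  # source geometry
                  sdir, disc_c, disc_u, disc_w, disc_r,
                  # scene arrays
                  v0, e1, e2, tnormal, tri_elem,
                  elem_rho, elem_tau, elem_spec, elem_leaf,
                  # leaf uv mapping / patch grids
                  tri_uv0, tri_uv1, tri_uv2,
                  patch_off, patch_nu, patch_nv, patch_u0, patch_v0, pitch,
                  # bvh
                  bmin, bmax, left, right, start, count, order,
                  # outputs
                  elem_s1, elem_s2, absorbed, patch_counts):
    """Trace ``n_rays`` packets from one source; returns (escaped, truncated).

    mode 0 = collimated beam from a disc normal to ``sdir``;
    mode 1 = diffuse sky: origins on a horizontal disc, cosine-weighted down;
    mode 2 = Lambertian lamp disc emitting downward.
    Tallies are integer packet-impact counts; flux weights are applied by the
    caller so the ledger closes exactly.
    """
    np.random.seed(seed)
    escaped = 0
    truncated = 0
    loc_elem = np.empty(max_impacts, np.int64)
    loc_cnt = np.empty(max_impacts, np.int64)

    for _ in range(n_rays):
        # --- sample origin & direction
        r1 = np.random.random()
        r2 = np.random.random()
        rad = disc_r * math.sqrt(r1)
        ang = 2.0 * math.pi * r2
        ox = disc_c[0] + rad * (math.cos(ang) * disc_u[0] + math.sin(ang) * disc_w[0])
        oy = disc_c[1] + rad * (math.cos(ang) * disc_u[1] + math.sin(ang) * disc_w[1])
        oz = disc_c[2] + rad * (math.cos(ang) * disc_u[2] + math.sin(ang) * disc_w[2])
        if mode == 0:
            dx, dy, dz = sdir[0], sdir[1], sdir[2]
        else:
            # downward cosine-weighted (sky dome radiance / Lambertian lamp)
            dx, dy, dz = _cosine_dir(0.0, 0.0, -1.0)

        nloc = 0
        alive = True
        impacts = 0
        while alive and impacts < max_impacts:
            t, i = _hit_bvh(ox, oy, oz, dx, dy, dz, v0, e1, e2,
                            bmin, bmax, left, right, start, count, order)
            if i < 0:
                escaped += 1
                alive = False
                break
            impacts += 1
            e = tri_elem[i]
            # incident tally (both faces)
            found = False
            for k in range(nloc):
                if loc_elem[k] == e:
                    loc_cnt[k] += 1
                    found = True
                    break
            if not found:
                loc_elem[nloc] = e
                loc_cnt[nloc] = 1
                nloc += 1

            px = ox + t * dx
            py = oy + t * dy
            pz = oz + t * dz

            if elem_leaf[e] >= 0:
                # leaf detector patch from the hit point's leaf-local uv
                li = elem_leaf[e]
                # barycentric via precomputed per-vertex uv
                tv0x = v0[i, 0]
                tv0y = v0[i, 1]
                tv0z = v0[i, 2]
                rx = px - tv0x
                ry = py - tv0y
                rz = pz - tv0z
                a11 = e1[i, 0] * e1[i, 0] + e1[i, 1] * e1[i, 1] + e1[i, 2] * e1[i, 2]
                a12 = e1[i, 0] * e2[i, 0] + e1[i, 1] * e2[i, 1] + e1[i, 2] * e2[i, 2]
                a22 = e2[i, 0] * e2[i, 0] + e2[i, 1] * e2[i, 1] + e2[i, 2] * e2[i, 2]
                det = a11 * a22 - a12 * a12
                if det > 0.0:
                    re1 = rx * e1[i, 0] + ry * e1[i, 1] + rz * e1[i, 2]
                    re2 = rx * e2[i, 0] + ry * e2[i, 1] + rz * e2[i, 2]
                    bu = (a22 * re1 - a12 * re2) / det
                    bv = (a11 * re2 - a12 * re1) / det
                    hu = (1.0 - bu - bv) * tri_uv0[i, 0] + bu * tri_uv1[i, 0] + bv * tri_uv2[i, 0]
                    hv = (1.0 - bu - bv) * tri_uv0[i, 1] + bu * tri_uv1[i, 1] + bv * tri_uv2[i, 1]
                    iu = int((hu - patch_u0[li]) / pitch)
                    iv = int((hv - patch_v0[li]) / pitch)
                    if iu < 0:
                        iu = 0
                    if iv < 0:
                        iv = 0
                    if iu >= patch_nu[li]:
                        iu = patch_nu[li] - 1
                    if iv >= patch_nv[li]:
                        iv = patch_nv[li] - 1
                    patch_counts[patch_off[li] + iv * patch_nu[li] + iu] += 1

            # --- scatter
            xi = np.random.random()
            rho = elem_rho[e]
            tau = elem_tau[e]
            nx = tnormal[i, 0]
            ny = tnormal[i, 1]
            nz = tnormal[i, 2]
            # incident-side normal
            if dx * nx + dy * ny + dz * nz > 0.0:
                nx = -nx
                ny = -ny
                nz = -nz
            if xi < rho:
                dx, dy, dz = _cosine_dir(nx, ny, nz)
            elif xi < rho + tau:
                if elem_spec[e] == 1:
                    pass  # direction preserved (glazing)
                else:
                    dx, dy, dz = _cosine_dir(-nx, -ny, -nz)
            else:
                absorbed[e] += 1
                alive = False
            ox = px + _EPS_HIT * dx
            oy = py + _EPS_HIT * dy
            oz = pz + _EPS_HIT * dz

        if alive and impacts >= max_impacts:
            truncated += 1

        for k in range(nloc):
            c = loc_cnt[k]
            elem_s1[loc_elem[k]] += c
            elem_s2[loc_elem[k]] += c * c

    return escaped, truncated


# ----------------------------------------------------------------------------
# scene compilation & the public trace
# ----------------------------------------------------------------------------

class _CompiledScene:
    def __init__(self, mesh: TriangleMesh, materials: dict, pitch: float):
        self.mesh = mesh
        self.accel = MeshAccel(mesh)
        tv = mesh.vertices[mesh.triangles]
        n = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self.tnormal = np.ascontiguousarray(n / norm)

        ids = np.unique(mesh.element_id)
        self.element_ids = ids
        self.idx_of = {int(e): i for i, e in enumerate(ids)}
        k = len(ids)
        self.kind = np.empty(k, dtype="U8")
        self.area = np.zeros(k)
        areas = mesh.triangle_areas()
        self.tri_elem = np.empty(mesh.n_triangles, np.int64)
        for i, e in enumerate(ids):
            mask = mesh.element_id == e
            self.kind[i] = mesh.element_kind[mask][0]
            self.area[i] = areas[mask].sum()
            self.tri_elem[mask] = i

        self.rho = np.zeros(k)
        self.tau = np.zeros(k)
        self.spec = np.zeros(k, np.int64)
        for i in range(k):
            kind = str(self.kind[i])
            if kind not in materials:
                raise MaterialError(f"no optical material for kind '{kind}'")
            m = materials[kind]
            self.rho[i] = m.reflectance
            self.tau[i] = m.transmittance
            self.spec[i] = 0 if m.diffuse_transmission else 1

        # leaf-local uv frames and patch grids
        leaf_ids = [int(e) for i, e in enumerate(ids) if self.kind[i] == "leaf"]
        self.elem_leaf = np.full(k, -1, np.int64)
        m_tri = mesh.n_triangles
        self.tri_uv0 = np.zeros((m_tri, 2))
        self.tri_uv1 = np.zeros((m_tri, 2))
        self.tri_uv2 = np.zeros((m_tri, 2))
        off, nu_l, nv_l, u0_l, v0_l = [], [], [], [], []
        total = 0
        self.leaf_elements = leaf_ids
        for li, e in enumerate(leaf_ids):
            self.elem_leaf[self.idx_of[e]] = li
            mask = mesh.element_id == e
            vids = np.unique(mesh.triangles[mask])
            pts = mesh.vertices[vids]
            centroid = pts.mean(axis=0)
            # plane axes from the largest triangle's edges
            sub = np.where(mask)[0]
            big = sub[np.argmax(areas[sub])]
            a = tv[big, 1] - tv[big, 0]
            a = a / np.linalg.norm(a)
            nrm = self.tnormal[big]
            b = np.cross(nrm, a)
            uv = np.stack([(pts - centroid) @ a, (pts - centroid) @ b], axis=1)
            uv_of = {int(v): uv[j] for j, v in enumerate(vids)}
            for ti in sub:
                t0, t1, t2 = mesh.triangles[ti]
                self.tri_uv0[ti] = uv_of[int(t0)]
                self.tri_uv1[ti] = uv_of[int(t1)]
                self.tri_uv2[ti] = uv_of[int(t2)]
            u0, v0 = uv.min(axis=0)
            u1, v1 = uv.max(axis=0)
            nu = max(1, int(math.ceil((u1 - u0) / pitch)))
            nv = max(1, int(math.ceil((v1 - v0) / pitch)))
            off.append(total)
            nu_l.append(nu)
            nv_l.append(nv)
            u0_l.append(u0)
            v0_l.append(v0)
            total += nu * nv
        self.patch_off = np.asarray(off, np.int64) if off else np.zeros(0, np.int64)
        self.patch_nu = np.asarray(nu_l, np.int64) if off else np.zeros(0, np.int64)
        self.patch_nv = np.asarray(nv_l, np.int64) if off else np.zeros(0, np.int64)
        self.patch_u0 = np.asarray(u0_l) if off else np.zeros(0)
        self.patch_v0 = np.asarray(v0_l) if off else np.zeros(0)
        self.n_patches = total

        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        self.bbox = (lo, hi)
        self.bound_center = 0.5 * (lo + hi)
        self.bound_radius = 0.5 * float(np.linalg.norm(hi - lo))


def _ortho_frame(d):
    helper = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    return u, w


def _beam_disc(scene: _CompiledScene, direction):
    """Tight source disc normal to the beam, covering the scene projection."""
    d = np.asarray(direction, float)
    u, w = _ortho_frame(d)
    verts = scene.mesh.vertices
    rel = verts - scene.bound_center
    pu = rel @ u
    pw = rel @ w
    radius = float(np.sqrt(pu ** 2 + pw ** 2).max()) * 1.01 + 1e-6
    # push the disc centre outside the scene against the beam
    along = rel @ d
    center = scene.bound_center + (along.min() - 0.05 * scene.bound_radius - 0.01) * d
    return center, u, w, radius


def _split_rays(n_total, fluxes):
    """Allocate rays to sources proportional to flux (at least 1 per live source)."""
    fluxes = np.asarray(fluxes, float)
    alloc = np.zeros(len(fluxes), int)
    live = fluxes > 0
    if live.any():
        share = fluxes[live] / fluxes[live].sum()
        alloc[live] = np.maximum(1, np.round(share * n_total).astype(int))
    return alloc


def trace(mesh: TriangleMesh, materials: dict, illumination,
          config: TraceConfig | None = None,
          keep_patches: bool = False) -> IrradianceMap:
    """Monte Carlo trace of all configured sources through the scene.

    ``materials`` maps element kind -> :class:`OpticalMaterial`; every kind
    present in the mesh must have one. Deterministic given
    ``config.rng_seed``. The returned map carries per-element incident flux
    and SE; PPFD is flux / one-sided element area.
    """
    if config is None:
        config = TraceConfig()
    scene = _CompiledScene(mesh, materials, config.detector_pitch)
    k = len(scene.element_ids)

    sources = []   # (mode, sdir, disc_c, disc_u, disc_w, disc_r, flux)
    beam = getattr(illumination, "beam", None)
    sky = getattr(illumination, "sky", None)
    lamp = getattr(illumination, "lamp", None)
    lo, hi = scene.bbox

    if beam is not None and beam.ppfd_normal > 0:
        d = np.asarray(beam.direction, float)
        d = d / np.linalg.norm(d)
        c, u, w, r = _beam_disc(scene, d)
        flux = beam.ppfd_normal * math.pi * r * r
        sources.append((0, d, c, u, w, r, flux))
    if sky is not None and sky.horizontal_ppfd > 0:
        # horizontal emitting disc above the scene; cosine-weighted downward
        # directions reproduce a uniform-radiance dome (exact for horizontal
        # surfaces under the disc, approximate at grazing incidence on walls,
        # hence the extra radius margin proportional to scene height)
        r = (float(np.linalg.norm((hi - lo)[:2])) / 2.0 * 1.05
             + 0.3 * float(hi[2] - lo[2]) + 1e-6)
        c = np.array([(lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2, hi[2] + 0.01])
        u = np.array([1.0, 0, 0])
        w = np.array([0, 1.0, 0])
        flux = sky.horizontal_ppfd * math.pi * r * r
        sources.append((1, np.array([0, 0, -1.0]), c, u, w, r, flux))
    if lamp is not None and lamp.total_flux > 0:
        u = np.array([1.0, 0, 0])
        w = np.array([0, 1.0, 0])
        sources.append((2, np.array([0, 0, -1.0]), np.asarray(lamp.center, float),
                        u, w, lamp.radius, lamp.total_flux))

    elem_flux = np.zeros(k)
    elem_var = np.zeros(k)
    absorbed_flux = np.zeros(k)
    escaped_flux = 0.0
    truncated_flux = 0.0
    emitted = 0.0
    patch_flux = np.zeros(scene.n_patches)
    total_rays = 0

    alloc = _split_rays(config.n_rays, [s[6] for s in sources])
    ss = np.random.SeedSequence(config.rng_seed)
    seeds = ss.generate_state(max(len(sources), 1)) % np.uint32(2 ** 31 - 1)

    for (src, n_s, seed) in zip(sources, alloc, seeds):
        if n_s == 0:
            continue
        mode, sdir, c, u, w, r, flux = src
        weight = flux / n_s
        elem_s1 = np.zeros(k, np.int64)
        elem_s2 = np.zeros(k, np.int64)
        absorbed = np.zeros(k, np.int64)
        patch_counts = np.zeros(max(scene.n_patches, 1), np.int64)
        escaped, truncated = _trace_source(
            mode, n_s, int(seed), config.max_impacts,
            np.ascontiguousarray(sdir), np.ascontiguousarray(c),
            np.ascontiguousarray(u), np.ascontiguousarray(w), float(r),
            scene.accel.v0, scene.accel.e1, scene.accel.e2,
            scene.tnormal, scene.tri_elem,
            scene.rho, scene.tau, scene.spec, scene.elem_leaf,
            scene.tri_uv0, scene.tri_uv1, scene.tri_uv2,
            scene.patch_off, scene.patch_nu, scene.patch_nv,
            scene.patch_u0, scene.patch_v0, config.detector_pitch,
            scene.accel.node_min, scene.accel.node_max, scene.accel.node_left,
            scene.accel.node_right, scene.accel.node_start,
            scene.accel.node_count, scene.accel.tri_order,
            elem_s1, elem_s2, absorbed, patch_counts)
        emitted += flux
        total_rays += int(n_s)
        elem_flux += elem_s1 * weight
        # sample variance of the per-packet contribution
        var = (elem_s2 - elem_s1.astype(float) ** 2 / n_s)
        if n_s > 1:
            var *= n_s / (n_s - 1.0)
        elem_var += np.maximum(var, 0.0) * weight ** 2
        absorbed_flux += absorbed * weight
        escaped_flux += escaped * weight
        truncated_flux += truncated * weight
        if scene.n_patches:
            patch_flux += patch_counts[:scene.n_patches] * weight

    absorbed_by_kind = {}
    for i, e in enumerate(scene.element_ids):
        kind = str(scene.kind[i])
        absorbed_by_kind[kind] = absorbed_by_kind.get(kind, 0.0) + absorbed_flux[i]

    ledger = {
        "emitted": emitted,
        "absorbed_by_kind": absorbed_by_kind,
        "absorbed": float(sum(absorbed_by_kind.values())),
        "escaped": escaped_flux,
        "truncated": truncated_flux,
    }

    patch_grids = {}
    if keep_patches:
        for li, e in enumerate(scene.leaf_elements):
            nu = scene.patch_nu[li]
            nv = scene.patch_nv[li]
            sl = patch_flux[scene.patch_off[li]:scene.patch_off[li] + nu * nv]
            patch_grids[e] = (sl.reshape(nv, nu)
                              / config.detector_pitch ** 2)

    return IrradianceMap(
        element_ids=scene.element_ids, element_kind=scene.kind,
        element_area=scene.area, incident_flux=elem_flux,
        incident_se=np.sqrt(elem_var), ledger=ledger, n_rays=total_rays,
        patch_grids=patch_grids)


@njit(cache=True, error_model="numpy")
def _disc_visibility(px, py, pz, cx, cy, cz, radius, n_samples, seed,
                     v0, e1, e2, bmin, bmax, left, right, start, count, order):
    """Fraction of a horizontal disc visible from a point through the mesh."""
    np.random.seed(seed)
    cnt = 0
    for _ in range(n_samples):
        r = radius * math.sqrt(np.random.random())
        a = 2.0 * math.pi * np.random.random()
        dx = cx + r * math.cos(a) - px
        dy = cy + r * math.sin(a) - py
        dz = cz - pz
        L = math.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= L
        dy /= L
        dz /= L
        t, i = _hit_bvh(px, py, pz, dx, dy, dz, v0, e1, e2,
                        bmin, bmax, left, right, start, count, order)
        if i < 0 or t > L:
            cnt += 1
    return cnt / n_samples


def disc_visibility(point, disc_center, disc_radius, accel: MeshAccel,
                    n_samples: int = 150, seed: int = 0) -> float:
    """Monte Carlo visible fraction of a source disc from a scene point.

    Used to place virtual quantum sensors relative to the canopy (a point
    with visibility ~0 sits in full shadow of the foliage)."""
    p = np.asarray(point, float)
    c = np.asarray(disc_center, float)
    return float(_disc_visibility(
        p[0], p[1], p[2], c[0], c[1], c[2], float(disc_radius),
        n_samples, seed, accel.v0, accel.e1, accel.e2,
        accel.node_min, accel.node_max, accel.node_left, accel.node_right,
        accel.node_start, accel.node_count, accel.tri_order))


def leaf_ppfd_table(irradiance: IrradianceMap, leaves) -> pd.DataFrame:
    """Per-leaf mean PPFD and MC standard error, joined by leaf id."""
    rows = []
    for rec in leaves:
        if int(rec.leaf_id) not in irradiance._index:
            raise KeyError(f"leaf {rec.leaf_id} not in irradiance map")
        rows.append({
            "leaf_id": rec.leaf_id,
            "ppfd": irradiance.ppfd(rec.leaf_id),
            "se": irradiance.ppfd_se(rec.leaf_id),
        })
    return pd.DataFrame(rows, columns=["leaf_id", "ppfd", "se"])


def calibrate_lamp(mesh: TriangleMesh, materials: dict, illumination,
                   top_sensor_element: int, target_ppfd_at_top: float,
                   config: TraceConfig | None = None):
    """Scale the lamp flux so the traced top sensor reads the target PPFD.

    Transport is linear in source flux, so one trace plus a scalar rescale
    suffices. Returns ``(total_flux, scaled IrradianceMap)``.
    """
    if target_ppfd_at_top < 0:
        raise ValueError("target must be >= 0")
    if illumination.lamp is None:
        raise ValueError("illumination has no lamp")
    if target_ppfd_at_top == 0.0:
        base = trace(mesh, materials, illumination, config)
        return 0.0, base.scaled(0.0)
    base = trace(mesh, materials, illumination, config)
    reading = base.ppfd(top_sensor_element)
    if reading <= 0:
        raise RuntimeError("top sensor receives no flux; cannot calibrate")
    factor = target_ppfd_at_top / reading
    return illumination.lamp.total_flux * factor, base.scaled(factor)
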