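"""Procedural 3D mango plant geometry.

Builds a triangle-mesh model of a young, vase-shaped greenhouse mango from
morphological rules: a leaf-area allometry (area from blade length and width),
spiral phyllotaxis with a near-golden mean divergence angle, and a Y-shaped
branch architecture (a short main stem splitting into two branches per level).
The mesh plus a per-leaf table feed the ray tracer and the photosynthesis
model downstream.

Coordinate convention (shared by every module): metres, right-handed, z up,
+y = geographic north, plant base at the origin.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IRWIN_DIVERGENCE_ANGLES_DEG",
    "ALLOMETRY_COEFFS",
    "LeafRecord",
    "PlantConfig",
    "TriangleMesh",
    "leaf_area_from_dimensions",
    "phyllotaxis_azimuths",
    "build_plant",
    "random_flat_leaf_field",
    "concat_meshes",
    "make_box_shell",
    "make_quad",
    "make_disc",
    "write_obj",
    "read_obj",
    "write_ply",
    "write_leaf_table",
    "read_leaf_table",
]

#: Measured divergence angles (degrees) between eleven successive leaf pairs
#: of a two-year-old 'Irwin' mango; their mean, 137.6 deg, is close to the
#: golden angle (137.5 deg) typical of spiral phyllotaxis.
IRWIN_DIVERGENCE_ANGLES_DEG = (
    151.5, 133.2, 141.5, 157.6, 129.9, 122.1, 138.0, 138.8, 124.4, 150.9, 125.9,
)

#: Coefficients of the non-destructive leaf-area allometry for 'Irwin' mango,
#: LA = c0 + c1*W + c2*L^2 + c3*W^2 with L, W in cm and LA in cm^2.
ALLOMETRY_COEFFS = (-14.623, 8.074, 0.085, 0.452)

#: One-sided leaf area of the reference two-year-old plant, cm^2.
REFERENCE_TOTAL_LEAF_AREA_CM2 = 4194.84

ELEMENT_KINDS = ("leaf", "stem", "pot", "wall", "floor", "lamp", "sensor")


class AllometryDomainError(ValueError):
    """Leaf dimensions outside the calibration range of the area model."""


@dataclass(frozen=True)
class LeafRecord:
    """Morphology and placement of a single leaf."""

    leaf_id: int
    length: float            # blade length, cm
    width: float             # blade max width, cm
    petiole_length: float    # cm
    allometric_area: float   # one-sided area, cm^2
    azimuth: float           # midrib compass azimuth, deg in [0, 360)
    inclination: float       # midrib angle above horizontal, deg
    attachment_height: float  # z of petiole attachment, m
    branch_id: int

    def __post_init__(self):
        if self.allometric_area <= 0:
            raise ValueError("allometric_area must be positive")
        if self.length <= 0 or self.width <= 0:
            raise ValueError("leaf dimensions must be positive")
        if not (0.0 <= self.azimuth < 360.0):
            raise ValueError("azimuth must lie in [0, 360)")


@dataclass
class PlantConfig:
    """Parameters of the procedural plant generator.

    ``divergence_angles`` is either an explicit sequence of per-step angles in
    degrees (cycled if shorter than a branch's leaf count) or a ``(mean, sd)``
    pair from which angles are drawn. Leaf dimension ranges are in cm; branch
    lengths/diameters in m.
    """

    n_leaves: int = 52
    divergence_angles: object = (137.6, 0.0)
    leaf_length_range: tuple = (18.0, 26.0)
    leaf_width_range: tuple = (4.5, 6.5)
    petiole_length_range: tuple = (2.5, 4.5)
    inclination_range: tuple = (-30.0, 45.0)
    branch_levels: int = 2
    branch_lengths: tuple = (0.35, 0.35)
    branch_diameters: tuple = (0.025, 0.015)
    stem_length: float = 0.5
    stem_diameter: float = 0.025
    pot_height: float = 0.40
    pot_diameter: float = 0.30
    branch_tilts: tuple = (25.0, 35.0)   # deg from vertical per level
    target_total_leaf_area: float | None = REFERENCE_TOTAL_LEAF_AREA_CM2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        for name in ("leaf_length_range", "leaf_width_range",
                     "petiole_length_range", "inclination_range"):
            lo, hi = getattr(self, name)
            if not (hi >= lo):
                raise ValueError(f"{name} is degenerate")
        if self.leaf_length_range[0] <= 0 or self.leaf_width_range[0] <= 0:
            raise ValueError("leaf dimension ranges must be positive")
        if self.branch_levels < 1:
            raise ValueError("branch_levels must be >= 1")
        if len(self.branch_lengths) < self.branch_levels:
            raise ValueError("need a branch length per level")
        if isinstance(self.divergence_angles, (list, tuple)) and \
                len(self.divergence_angles) == 0:
            raise ValueError("divergence_angles must be non-empty")


@dataclass
class TriangleMesh:
    """Indexed triangle soup with per-triangle element identity.

    ``element_id`` groups triangles into named scene elements (one leaf, one
    stem segment, a wall...); ``element_kind`` tags each triangle with one of
    ``ELEMENT_KINDS``. Leaf element ids coincide with ``LeafRecord.leaf_id``.
    """

    vertices: np.ndarray          # (n, 3) float64, metres
    triangles: np.ndarray         # (m, 3) int32
    element_id: np.ndarray        # (m,) int32
    element_kind: np.ndarray      # (m,) unicode

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int32)
        self.element_id = np.ascontiguousarray(self.element_id, dtype=np.int32)
        self.element_kind = np.asarray(self.element_kind, dtype="U8")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def element_ids(self) -> np.ndarray:
        return np.unique(self.element_id)

    def kind_of(self, element: int) -> str:
        mask = self.element_id == element
        if not mask.any():
            raise KeyError(f"no element {element}")
        return str(self.element_kind[mask][0])

    def element_area(self, element: int) -> float:
        """One-sided surface area of an element, m^2."""
        mask = self.element_id == element
        if not mask.any():
            raise KeyError(f"no element {element}")
        return float(self.triangle_areas()[mask].sum())

    def element_centroid(self, element: int) -> np.ndarray:
        mask = self.element_id == element
        areas = self.triangle_areas()[mask]
        cent = self.vertices[self.triangles[mask]].mean(axis=1)
        return (cent * areas[:, None]).sum(axis=0) / areas.sum()


# ----------------------------------------------------------------------------
# allometry & phyllotaxis
# ----------------------------------------------------------------------------

def leaf_area_from_dimensions(length: float, width: float) -> float:
    """One-sided leaf area (cm^2) from blade length and width (cm).

    Evaluates the mango allometry LA = c0 + c1*W + c2*L^2 + c3*W^2. Raises
    :class:`AllometryDomainError` when the polynomial goes non-positive
    (dimensions outside the calibration range); the result is never clamped,
    since a silently clamped area would corrupt area-weighted integration.
    """
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    c0, c1, c2, c3 = ALLOMETRY_COEFFS
    area = c0 + c1 * width + c2 * length ** 2 + c3 * width ** 2
    if area <= 0:
        raise AllometryDomainError(
            f"allometric area {area:.3f} cm^2 <= 0 for L={length}, W={width}")
    return area


def phyllotaxis_azimuths(divergence_angles, start_azimuth: float = 0.0) -> np.ndarray:
    """Cumulative leaf azimuths (deg, mod 360) of a phyllotactic spiral.

    ``azimuth[0] = start_azimuth`` and each subsequent leaf is rotated by the
    next divergence angle, so the output has one more entry than the input.
    """
    angles = np.asarray(divergence_angles, dtype=float)
    if angles.size == 0:
        raise ValueError("divergence_angles must be non-empty")
    az = np.empty(angles.size + 1)
    az[0] = start_azimuth
    az[1:] = start_azimuth + np.cumsum(angles)
    return np.mod(az, 360.0)


# ----------------------------------------------------------------------------
# primitive meshes
# ----------------------------------------------------------------------------

def _mesh_from_parts(verts, tris, elem, kind) -> TriangleMesh:
    tris = np.asarray(tris, dtype=np.int32)
    m = len(tris)
    return TriangleMesh(
        vertices=np.asarray(verts, float),
        triangles=tris,
        element_id=np.full(m, elem, np.int32),
        element_kind=np.full(m, kind, dtype="U8"),
    )


def make_quad(center, size, normal_axis: str = "z", element: int = 0,
              kind: str = "sensor") -> TriangleMesh:
    """Axis-aligned square quad (two triangles) centred at ``center``."""
    c = np.asarray(center, float)
    h = size / 2.0
    if normal_axis == "z":
        offs = np.array([[-h, -h, 0], [h, -h, 0], [h, h, 0], [-h, h, 0]])
    elif normal_axis == "x":
        offs = np.array([[0, -h, -h], [0, h, -h], [0, h, h], [0, -h, h]])
    else:
        offs = np.array([[-h, 0, -h], [h, 0, -h], [h, 0, h], [-h, 0, h]])
    verts = c + offs
    tris = [[0, 1, 2], [0, 2, 3]]
    return _mesh_from_parts(verts, tris, element, kind)


def make_disc(center, radius, element: int, kind: str, n_seg: int = 24,
              normal=(0, 0, -1)) -> TriangleMesh:
    """Horizontal disc fan (lamp emitter face)."""
    c = np.asarray(center, float)
    ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    rim = c + radius * np.stack([np.cos(ang), np.sin(ang), np.zeros(n_seg)], axis=1)
    verts = np.vstack([c, rim])
    tris = [[0, 1 + i, 1 + (i + 1) % n_seg] for i in range(n_seg)]
    return _mesh_from_parts(verts, tris, element, kind)


def _make_tube(p0, p1, radius, element, kind, n_seg: int = 8) -> TriangleMesh:
    """Open cylinder between two points."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / length
    # orthonormal frame around axis
    helper = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    ring = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))
    verts = np.vstack([p0 + ring, p1 + ring])
    tris = []
    for i in range(n_seg):
        j = (i + 1) % n_seg
        tris.append([i, j, n_seg + i])
        tris.append([j, n_seg + j, n_seg + i])
    return _mesh_from_parts(verts, tris, element, kind)


def make_box_shell(xmin, xmax, ymin, ymax, zmin, zmax, wall_element: int,
                   floor_element: int | None = None,
                   include_floor: bool = True,
                   include_ceiling: bool = True) -> TriangleMesh:
    """Rectangular enclosure: four walls, optional floor/ceiling.

    Floor triangles get their own element id and kind ``floor``; everything
    else is kind ``wall``.
    """
    v = np.array([
        [xmin, ymin, zmin], [xmax, ymin, zmin], [xmax, ymax, zmin], [xmin, ymax, zmin],
        [xmin, ymin, zmax], [xmax, ymin, zmax], [xmax, ymax, zmax], [xmin, ymax, zmax],
    ], float)
    wall_quads = [(0, 1, 5, 4), (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7)]
    if include_ceiling:
        wall_quads.append((4, 5, 6, 7))
    tris, elem, kind = [], [], []
    for q in wall_quads:
        tris += [[q[0], q[1], q[2]], [q[0], q[2], q[3]]]
        elem += [wall_element] * 2
        kind += ["wall"] * 2
    if include_floor:
        fe = wall_element if floor_element is None else floor_element
        tris += [[0, 1, 2], [0, 2, 3]]
        elem += [fe] * 2
        kind += ["floor"] * 2
    return TriangleMesh(v, np.array(tris, np.int32),
                        np.array(elem, np.int32), np.array(kind, dtype="U8"))


def concat_meshes(*meshes: TriangleMesh) -> TriangleMesh:
    """Concatenate meshes; element ids are kept as-is (caller keeps them unique)."""
    meshes = [m for m in meshes if m is not None and m.n_triangles > 0]
    if not meshes:
        raise ValueError("nothing to concatenate")
    verts, tris, elems, kinds = [], [], [], []
    off = 0
    for m in meshes:
        verts.append(m.vertices)
        tris.append(m.triangles + off)
        elems.append(m.element_id)
        kinds.append(m.element_kind)
        off += len(m.vertices)
    return TriangleMesh(np.vstack(verts), np.vstack(tris),
                        np.concatenate(elems), np.concatenate(kinds))


# ----------------------------------------------------------------------------
# leaf blade geometry
# ----------------------------------------------------------------------------

_LANCE_STATIONS = 7          # stations along the midrib -> 10 triangles
_LANCE_WIDTH_AT = 0.4        # max width at 40% of length from the base


def _lance_half_width(s: np.ndarray) -> np.ndarray:
    """Normalized lanceolate half-width profile: two mirrored quadratic arcs
    peaking at ``_LANCE_WIDTH_AT`` of the blade length, zero at base and tip."""
    s0 = _LANCE_WIDTH_AT
    out = np.where(
        s < s0,
        1.0 - ((s - s0) / s0) ** 2,
        1.0 - ((s - s0) / (1.0 - s0)) ** 2,
    )
    return np.clip(out, 0.0, 1.0)


def _leaf_blade_mesh(attach, azimuth_deg, inclination_deg, length_m,
                     petiole_m, area_m2, element: int):
    """Flat lanceolate blade triangulated along the midrib.

    The blade width is solved so that the *triangulated* one-sided area equals
    ``area_m2`` exactly (polygon area is linear in the width scale), keeping
    the mesh/record area consistency tight by construction.
    """
    az = math.radians(azimuth_deg)
    inc = math.radians(inclination_deg)
    d = np.array([math.sin(az) * math.cos(inc),
                  math.cos(az) * math.cos(inc),
                  math.sin(inc)])
    cross = np.array([math.cos(az), -math.sin(az), 0.0])
    base = np.asarray(attach, float) + petiole_m * d

    s = np.linspace(0.0, 1.0, _LANCE_STATIONS)
    h = _lance_half_width(s)
    # unit-width polygon area along the triangulation (trapezoid exact)
    # full width at station k is 2*half_w*h[k]; strip area = half_w * unit_area
    unit_area = np.trapezoid(2.0 * h, s * length_m)
    half_w = area_m2 / unit_area

    verts = [base]                       # base point (s=0, h=0)
    for k in range(1, _LANCE_STATIONS - 1):
        p = base + s[k] * length_m * d
        verts.append(p - half_w * h[k] * cross)   # left
        verts.append(p + half_w * h[k] * cross)   # right
    verts.append(base + length_m * d)    # tip
    verts = np.asarray(verts)

    tris = [[0, 2, 1]]
    for k in range(_LANCE_STATIONS - 3):
        a = 1 + 2 * k
        tris += [[a, a + 1, a + 2], [a + 1, a + 3, a + 2]]
    tip = len(verts) - 1
    tris.append([tip - 2, tip - 1, tip])
    return _mesh_from_parts(verts, tris, element, "leaf")


# ----------------------------------------------------------------------------
# plant builder
# ----------------------------------------------------------------------------

def _resolve_divergence(config: PlantConfig, rng: np.random.Generator,
                        n: int) -> np.ndarray:
    da = config.divergence_angles
    if isinstance(da, (list, tuple, np.ndarray)) and len(da) == 2 and \
            not isinstance(da[0], (list, tuple)) and _looks_like_mean_sd(da):
        mean, sd = float(da[0]), float(da[1])
        if sd == 0.0:
            return np.full(n, mean)
        return rng.normal(mean, sd, size=n)
    arr = np.asarray(da, dtype=float).ravel()
    reps = int(np.ceil(n / arr.size))
    return np.tile(arr, reps)[:n]


def _looks_like_mean_sd(da) -> bool:
    # (mean, sd) vs a two-angle list: treat a pair whose second entry is small
    # (< 90) and a tuple type as mean/sd. Explicit lists of angles should be
    # passed as lists.
    return isinstance(da, tuple) and float(da[1]) < 90.0


def build_plant(config: PlantConfig) -> tuple[TriangleMesh, list[LeafRecord]]:
    """Generate the plant mesh (pot + stem + branches + leaves) and leaf table.

    Deterministic given ``config.rng_seed``. Leaves are distributed along the
    terminal branches in spiral order, the azimuth advancing by the configured
    divergence sequence; if ``target_total_leaf_area`` is set, per-leaf areas
    are uniformly rescaled (geometry by the square root of the factor) so the
    summed area matches the target exactly, preserving area fractions.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n = config.n_leaves
    lengths = rng.uniform(*config.leaf_length_range, size=n)
    widths = rng.uniform(*config.leaf_width_range, size=n)
    petioles = rng.uniform(*config.petiole_length_range, size=n)
    inclinations = rng.uniform(*config.inclination_range, size=n)
    areas = np.array([leaf_area_from_dimensions(L, W)
                      for L, W in zip(lengths, widths)])

    scale = 1.0
    if config.target_total_leaf_area is not None:
        scale = config.target_total_leaf_area / areas.sum()
        areas = areas * scale
        lengths = lengths * math.sqrt(scale)
        widths = widths * math.sqrt(scale)
        petioles = petioles * math.sqrt(scale)

    # --- branch skeleton -----------------------------------------------------
    pot_top = np.array([0.0, 0.0, config.pot_height])
    stem_top = pot_top + [0.0, 0.0, config.stem_length]
    base_azimuth = rng.uniform(0.0, 360.0)

    segments = []   # (p0, p1, radius) for stems/branches
    tips = [(stem_top, base_azimuth)]
    segments.append((pot_top, stem_top, config.stem_diameter / 2.0))
    for level in range(config.branch_levels):
        tilt = math.radians(config.branch_tilts[min(level, len(config.branch_tilts) - 1)])
        blen = config.branch_lengths[level]
        brad = config.branch_diameters[min(level, len(config.branch_diameters) - 1)] / 2.0
        new_tips = []
        spread = 180.0 if level == 0 else 110.0
        for p, az in tips:
            for k, daz in enumerate((-spread / 2.0, spread / 2.0)):
                a = math.radians(az + daz)
                d = np.array([math.sin(a) * math.sin(tilt),
                              math.cos(a) * math.sin(tilt),
                              math.cos(tilt)])
                q = p + blen * d
                segments.append((p, q, brad))
                new_tips.append(((p, q), az + daz))
        tips = [(pq[1], a) for pq, a in new_tips]
        terminal = new_tips
    terminal_branches = [pq for pq, _ in terminal]
    terminal_azimuths = [a % 360.0 for _, a in terminal]

    # --- leaf placement ------------------------------------------------------
    nb = len(terminal_branches)
    counts = [n // nb + (1 if i < n % nb else 0) for i in range(nb)]
    leaf_order = []          # (branch_idx, position fraction)
    for b, cnt in enumerate(counts):
        if cnt == 0:
            continue
        fr = np.linspace(0.25, 1.0, cnt) if cnt > 1 else np.array([1.0])
        for f in fr:
            leaf_order.append((b, f))

    records: list[LeafRecord] = []
    leaf_meshes = []
    per_branch_counter = {b: 0 for b in range(nb)}
    divergence_per_branch = {
        b: _resolve_divergence(config, rng, max(counts[b] - 1, 1))
        for b in range(nb)
    }
    branch_azimuth_seq = {
        b: phyllotaxis_azimuths(divergence_per_branch[b],
                                start_azimuth=terminal_azimuths[b])
        for b in range(nb)
    }

    for leaf_id, (b, f) in enumerate(leaf_order):
        p0, p1 = terminal_branches[b]
        attach = p0 + f * (np.asarray(p1) - np.asarray(p0))
        k = per_branch_counter[b]
        per_branch_counter[b] += 1
        azimuth = float(branch_azimuth_seq[b][k])
        rec = LeafRecord(
            leaf_id=leaf_id,
            length=float(lengths[leaf_id]),
            width=float(widths[leaf_id]),
            petiole_length=float(petioles[leaf_id]),
            allometric_area=float(areas[leaf_id]),
            azimuth=azimuth,
            inclination=float(inclinations[leaf_id]),
            attachment_height=float(attach[2]),
            branch_id=b,
        )
        records.append(rec)
        leaf_meshes.append(_leaf_blade_mesh(
            attach, rec.azimuth, rec.inclination,
            rec.length / 100.0, rec.petiole_length / 100.0,
            rec.allometric_area / 1e4, element=leaf_id))

    # --- woody parts & pot ---------------------------------------------------
    next_id = n
    woody = []
    for p0, p1, r in segments:
        woody.append(_make_tube(p0, p1, r, next_id, "stem"))
        next_id += 1
    pot = _make_tube([0, 0, 0], pot_top, config.pot_diameter / 2.0,
                     next_id, "pot", n_seg=16)
    next_id += 1

    mesh = concat_meshes(*leaf_meshes, *woody, pot)
    return mesh, records


def canopy_z_extent(mesh: TriangleMesh) -> tuple[float, float]:
    """Vertical extent (m) of the leaf elements."""
    mask = mesh.element_kind == "leaf"
    if not mask.any():
        raise ValueError("mesh has no leaves")
    z = mesh.vertices[mesh.triangles[mask]][:, :, 2]
    return float(z.min()), float(z.max())


# ----------------------------------------------------------------------------
# synthetic flat-leaf test canopies
# ----------------------------------------------------------------------------

def random_flat_leaf_field(n_leaves: int, total_area: float, box=1.0,
                           rng_seed: int = 0, z_range=(0.05, 0.95)):
    """Horizontal square leaves uniformly placed in a ``box x box`` column.

    A synthetic turbid-medium stand-in used for analytic radiative checks
    (Beer–Lambert gap fraction): ``n_leaves`` identical horizontal squares of
    summed one-sided area ``total_area`` (m^2), centres uniform over the box
    cross-section, so any point well inside the footprint sees a binomial
    number of occluding leaves.
    """
    rng = np.random.default_rng(rng_seed)
    side = math.sqrt(total_area / n_leaves)
    meshes = []
    for i in range(n_leaves):
        c = [rng.uniform(0, box), rng.uniform(0, box),
             rng.uniform(*z_range)]
        meshes.append(make_quad(c, side, "z", element=i, kind="leaf"))
    return concat_meshes(*meshes), side


# ----------------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------------

def write_obj(mesh: TriangleMesh, path) -> None:
    """Wavefront OBJ: one named object per element, kind in the material name."""
    ids = mesh.element_ids()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mangoray scene mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for e in ids:
            mask = mesh.element_id == e
            kind = mesh.element_kind[mask][0]
            fh.write(f"o elem_{e}\nusemtl {kind}\n")
            for t in mesh.triangles[mask]:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def read_obj(path) -> TriangleMesh:
    """Read a mesh written by :func:`write_obj` (element id/kind round-trip)."""
    verts, tris, elems, kinds = [], [], [], []
    cur_elem, cur_kind = 0, "leaf"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "o" and parts[1].startswith("elem_"):
                cur_elem = int(parts[1][5:])
            elif parts[0] == "usemtl":
                cur_kind = parts[1]
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
                tris.append(idx)
                elems.append(cur_elem)
                kinds.append(cur_kind)
    return TriangleMesh(np.array(verts), np.array(tris, np.int32),
                        np.array(elems, np.int32), np.array(kinds, dtype="U8"))


def write_ply(mesh: TriangleMesh, path) -> None:
    """Geometry-only PLY export via trimesh (element tags live in the OBJ)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    tm.export(str(path))


_LEAF_CSV_FIELDS = ["leaf_id", "length", "width", "petiole_length",
                    "allometric_area", "azimuth", "inclination",
                    "attachment_height", "branch_id"]


def write_leaf_table(records: list[LeafRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LEAF_CSV_FIELDS)
        for r in records:
            w.writerow([r.leaf_id, f"{r.length:.6f}", f"{r.width:.6f}",
                        f"{r.petiole_length:.6f}", f"{r.allometric_area:.6f}",
                        f"{r.azimuth:.9f}", f"{r.inclination:.6f}",
                        f"{r.attachment_height:.6f}", r.branch_id])


def read_leaf_table(path) -> list[LeafRecord]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(LeafRecord(
                leaf_id=int(row["leaf_id"]), length=float(row["length"]),
                width=float(row["width"]),
                petiole_length=float(row["petiole_length"]),
                allometric_area=float(row["allometric_area"]),
                azimuth=float(row["azimuth"]),
                inclination=float(row["inclination"]),
                attachment_height=float(row["attachment_height"]),
                branch_id=int(row["branch_id"])))
    return out
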