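"""Scene illumination: solar geometry, beam/diffuse partition, lamp sources.

All light is carried as PPFD (photosynthetic photon flux density,
umol photons m^-2 s^-1, band-integrated over 400-700 nm); there is no
spectral resolution. Natural light is a collimated solar beam plus a
uniform-radiance diffuse sky dome; artificial light is a Lambertian disc
lamp. Solar position follows the standard NOAA low-precision algorithm
(fractional-year Fourier series for declination and the equation of time),
good to a few hundredths of a degree — far tighter than the 0.5 deg contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

__all__ = [
    "SolarPosition",
    "SiteTime",
    "BeamSource",
    "SkySource",
    "LampSource",
    "SceneIllumination",
    "solar_position",
    "partition_ghi",
    "natural_illumination",
    "lamp_illumination",
    "sky_dome_patches",
    "SUWON_LATITUDE",
    "SUWON_LONGITUDE",
]

#: Experimental-farm site, Suwon, Korea. The source longitude was printed with
#: an impossible arc-minute value (> 60), so it is read as decimal 126.98 E.
SUWON_LATITUDE = 37.45
SUWON_LONGITUDE = 126.98


@dataclass(frozen=True)
class SolarPosition:
    zenith: float    # deg in [0, 180]; > 90 means sun below horizon
    azimuth: float   # deg in [0, 360), clockwise from north

    @property
    def below_horizon(self) -> bool:
        return self.zenith > 90.0

    def beam_direction(self) -> np.ndarray:
        """Unit propagation direction of the solar beam (pointing down-scene)."""
        z = math.radians(self.zenith)
        a = math.radians(self.azimuth)
        sun = np.array([math.sin(z) * math.sin(a),
                        math.sin(z) * math.cos(a),
                        math.cos(z)])
        return -sun


@dataclass(frozen=True)
class SiteTime:
    """Geographic position plus a local wall-clock time."""

    latitude: float          # deg, +N
    longitude: float         # deg, +E
    when: datetime           # naive local time
    utc_offset_hours: float  # local time = UTC + offset

    def __post_init__(self):
        if abs(self.latitude) > 90.0:
            raise ValueError("|latitude| must be <= 90")


@dataclass(frozen=True)
class BeamSource:
    direction: np.ndarray   # unit vector, propagation direction
    ppfd_normal: float      # PPFD on a plane normal to the beam


@dataclass(frozen=True)
class SkySource:
    horizontal_ppfd: float  # diffuse PPFD on a horizontal plane
    n_patches: int = 145    # dome discretization (diagnostic ledger)


@dataclass(frozen=True)
class LampSource:
    center: np.ndarray      # disc centre, m
    radius: float           # emitting disc radius, m
    total_flux: float       # umol s^-1, Lambertian downward emission


@dataclass(frozen=True)
class SceneIllumination:
    beam: BeamSource | None = None
    sky: SkySource | None = None
    lamp: LampSource | None = None

    def __post_init__(self):
        if self.beam is None and self.sky is None and self.lamp is None:
            raise ValueError("at least one light source required")
        for src, attr in ((self.beam, "ppfd_normal"),
                          (self.sky, "horizontal_ppfd"),
                          (self.lamp, "total_flux")):
            if src is not None and getattr(src, attr) < 0:
                raise ValueError("light source magnitudes must be >= 0")


# ----------------------------------------------------------------------------
# solar geometry (NOAA low-precision equations)
# ----------------------------------------------------------------------------

def _noaa_angles(utc: datetime) -> tuple[float, float]:
    """Solar declination (rad) and equation of time (minutes)."""
    doy = utc.timetuple().tm_yday
    hour = utc.hour + utc.minute / 60.0 + utc.second / 3600.0
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075
                       + 0.001868 * math.cos(gamma)
                       - 0.032077 * math.sin(gamma)
                       - 0.014615 * math.cos(2 * gamma)
                       - 0.040849 * math.sin(2 * gamma))
    decl = (0.006918
            - 0.399912 * math.cos(gamma)
            + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma)
            + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma)
            + 0.00148 * math.sin(3 * gamma))
    return decl, eqtime


def solar_position(site_time: SiteTime) -> SolarPosition:
    """Topocentric solar zenith and compass azimuth for a site and local time."""
    utc = site_time.when - timedelta(hours=site_time.utc_offset_hours)
    decl, eqtime = _noaa_angles(utc)
    minutes_utc = utc.hour * 60.0 + utc.minute + utc.second / 60.0
    true_solar_min = minutes_utc + eqtime + 4.0 * site_time.longitude
    ha = math.radians(true_solar_min / 4.0 - 180.0)   # hour angle

    lat = math.radians(site_time.latitude)
    cos_zen = (math.sin(lat) * math.sin(decl)
               + math.cos(lat) * math.cos(decl) * math.cos(ha))
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))

    # sun unit vector components in (east, north, up)
    east = -math.cos(decl) * math.sin(ha)
    north = math.sin(decl) * math.cos(lat) - math.cos(decl) * math.cos(ha) * math.sin(lat)
    azimuth = math.degrees(math.atan2(east, north)) % 360.0
    return SolarPosition(zenith=zenith, azimuth=azimuth)


def solar_noon(latitude: float, longitude: float, date,
               utc_offset_hours: float) -> datetime:
    """Local wall-clock time of solar noon (minimum zenith) for a date."""
    probe = datetime(date.year, date.month, date.day, 12, 0)
    utc = probe - timedelta(hours=utc_offset_hours)
    _, eqtime = _noaa_angles(utc)
    # true solar time = clock + eqtime + 4*lon - 60*tz; noon at tst = 720 min
    offset_min = eqtime + 4.0 * longitude - 60.0 * utc_offset_hours
    minutes = 720.0 - offset_min
    return datetime(date.year, date.month, date.day) + timedelta(minutes=minutes)


# ----------------------------------------------------------------------------
# source construction
# ----------------------------------------------------------------------------

def partition_ghi(global_horizontal_ppfd: float, diffuse_fraction: float,
                  zenith_deg: float) -> tuple[float, float]:
    """Split horizontal PPFD into (beam-normal, horizontal-diffuse) parts.

    Beam-normal PPFD is the direct horizontal component divided by
    cos(zenith); raises when the sun is at or below the horizon with a
    direct component still requested (cosine undefined).
    """
    if global_horizontal_ppfd < 0:
        raise ValueError("GHI PPFD must be >= 0")
    if not (0.0 <= diffuse_fraction <= 1.0):
        raise ValueError("diffuse_fraction must lie in [0, 1]")
    diffuse = diffuse_fraction * global_horizontal_ppfd
    direct_h = global_horizontal_ppfd - diffuse
    if direct_h == 0.0:
        return 0.0, diffuse
    if zenith_deg >= 90.0:
        raise ValueError("direct component undefined for sun at/below horizon")
    beam_normal = direct_h / math.cos(math.radians(zenith_deg))
    return beam_normal, diffuse


def natural_illumination(site_time: SiteTime, global_horizontal_ppfd: float,
                         diffuse_fraction: float = 0.3,
                         sky_patches: int = 145) -> SceneIllumination:
    """Solar beam + uniform diffuse dome for a site, time and direct/diffuse split.

    When the sun is below the horizon the diffuse fraction is forced to 1
    (the whole residual flux, usually zero, is treated as skylight).
    """
    pos = solar_position(site_time)
    f = 1.0 if pos.below_horizon else diffuse_fraction
    beam_normal, diffuse = partition_ghi(global_horizontal_ppfd, f, pos.zenith)
    beam = None
    if beam_normal > 0.0:
        beam = BeamSource(direction=pos.beam_direction(),
                          ppfd_normal=beam_normal)
    sky = SkySource(horizontal_ppfd=diffuse, n_patches=sky_patches)
    return SceneIllumination(beam=beam, sky=sky)


def lamp_illumination(height_above_canopy: float, total_flux: float,
                      radius: float, canopy_top: float = 0.0,
                      center_xy=(0.0, 0.0)) -> SceneIllumination:
    """Single Lambertian disc lamp ``height_above_canopy`` metres above the
    canopy top, emitting ``total_flux`` umol s^-1 downward."""
    if height_above_canopy <= 0 or radius <= 0:
        raise ValueError("lamp height and radius must be positive")
    if total_flux < 0:
        raise ValueError("total_flux must be >= 0")
    center = np.array([center_xy[0], center_xy[1],
                       canopy_top + height_above_canopy])
    return SceneIllumination(lamp=LampSource(center=center, radius=radius,
                                             total_flux=total_flux))


def sky_dome_patches(n_patches: int = 145):
    """Equal-solid-angle hemisphere discretization.

    Returns ``(directions, solid_angles, cos_weights)`` where ``directions``
    are unit vectors of patch centres (pointing up-sky), ``solid_angles`` sum
    to 2*pi and ``cos_weights`` are the per-patch integrals of cos(zenith)
    over the patch, summing to pi; a uniform-radiance sky of horizontal PPFD S
    assigns patch k a horizontal-flux share ``S * cos_weights[k] / pi``.
    """
    if n_patches < 1:
        raise ValueError("need at least one patch")
    # rings of equal zenith span, azimuthal counts proportional to ring area
    n_rings = max(1, int(round(math.sqrt(n_patches / 3.0))))
    edges = np.linspace(0.0, math.pi / 2.0, n_rings + 1)
    ring_area = np.cos(edges[:-1]) - np.cos(edges[1:])     # / 2pi
    counts = np.maximum(1, np.round(ring_area / ring_area.sum()
                                    * n_patches).astype(int))
    dirs, omegas, cws = [], [], []
    for (z0, z1), cnt in zip(zip(edges[:-1], edges[1:]), counts):
        zc = 0.5 * (z0 + z1)
        omega_ring = 2.0 * math.pi * (math.cos(z0) - math.cos(z1))
        cw_ring = math.pi * (math.cos(z0) ** 2 - math.cos(z1) ** 2)
        for k in range(cnt):
            az = 2.0 * math.pi * (k + 0.5) / cnt
            dirs.append([math.sin(zc) * math.sin(az),
                         math.sin(zc) * math.cos(az),
                         math.cos(zc)])
            omegas.append(omega_ring / cnt)
            cws.append(cw_ring / cnt)
    return np.asarray(dirs), np.asarray(omegas), np.asarray(cws)
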