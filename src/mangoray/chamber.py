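"""Closed-chamber gas exchange: drawdown analysis and forward simulation.

A sealed, well-mixed chamber of volume V at temperature T and pressure p
holds n = pV/(RT) moles of air. Plant net CO2 uptake F (umol s^-1) draws the
CO2 mole fraction C (umol mol^-1) down as dC/dt = -F/n (plus an optional
first-order leak toward ambient). The measurement computation inverts this:
the whole-plant photosynthetic rate per unit leaf area is the least-squares
slope of C over a centred averaging window (3 min default, robust to 1 Hz
sensor noise) times n, divided by the plant's one-sided leaf area. Drawdown
gives a positive rate; rising CO2 (dark respiration) gives a negative rate.

Forward simulation integrates the same ODE with classic RK4, allowing the
full light -> leaf PPFD -> leaf model -> canopy flux pipeline as the rate
model, so measurement and estimate can be round-tripped without physical
data. Humidity is ignored in the air-mole computation (a <= 2 percent effect
at greenhouse conditions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

R_GAS = 8.314  # J mol^-1 K^-1

__all__ = [
    "ChamberSpec",
    "GasExchangeTrace",
    "RateSeries",
    "air_moles",
    "drawdown_to_rate",
    "estimate_leak",
    "simulate_drawdown",
    "read_trace_csv",
    "write_rate_csv",
]


@dataclass(frozen=True)
class ChamberSpec:
    """Closed measurement chamber (1 x 1 x 2 m polycarbonate by default)."""

    dimensions: tuple = (1.0, 1.0, 2.0)   # m
    air_temperature: float = 305.15       # K (32 C)
    pressure: float = 101325.0            # Pa
    leak_coefficient: float = 0.0         # s^-1, first-order toward ambient
    ambient_co2: float = 400.0            # umol mol^-1

    def __post_init__(self):
        if self.volume <= 0 or self.air_temperature <= 0 or self.pressure <= 0:
            raise ValueError("chamber volume, temperature and pressure must be positive")
        if self.leak_coefficient < 0:
            raise ValueError("leak_coefficient must be >= 0")

    @property
    def volume(self) -> float:
        x, y, z = self.dimensions
        return x * y * z


@dataclass
class GasExchangeTrace:
    """CO2 mole-fraction time series inside the chamber."""

    time: np.ndarray   # s, monotone increasing
    co2: np.ndarray    # umol mol^-1

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.co2 = np.asarray(self.co2, float)
        if self.time.size < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.co2 < 0):
            raise ValueError("CO2 mole fraction cannot be negative")


@dataclass
class RateSeries:
    """Whole-plant photosynthetic rate derived over a sliding window."""

    time: np.ndarray    # s, window centres
    rate: np.ndarray    # umolCO2 m^-2(leaf) s^-1; positive = net uptake
    window: float       # s


def air_moles(chamber: ChamberSpec) -> float:
    """Moles of air in the chamber by the ideal-gas law, n = pV/(RT)."""
    return chamber.pressure * chamber.volume / (R_GAS * chamber.air_temperature)


def drawdown_to_rate(trace: GasExchangeTrace, chamber: ChamberSpec,
                     leaf_area: float, window: float = 180.0) -> RateSeries:
    """Whole-plant rate per leaf area from a chamber CO2 trace.

    rate(t) = (-slope of C over the centred window) * n_air / leaf_area,
    with the slope from an ordinary least-squares line fit. The leak
    correction ``+ k_leak * (ambient - C(t)) * n_air / leaf_area`` removes
    the drawdown that leakage (not the plant) caused while the chamber sat
    above ambient CO2, so a plant-free leaky chamber analyzes to zero rate.
    Defined only where the full window fits.
    """
    if leaf_area <= 0:
        raise ValueError("leaf_area must be positive")
    t = trace.time
    c = trace.co2
    if t[-1] - t[0] < window:
        raise ValueError("window longer than the trace")
    half = window / 2.0
    n_air = air_moles(chamber)

    # prefix sums make the sliding least-squares slope O(n)
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    valid = (t - t[0] >= half) & (t[-1] - t >= half)

    S0 = np.concatenate([[0.0], np.cumsum(np.ones_like(t))])
    St = np.concatenate([[0.0], np.cumsum(t)])
    Stt = np.concatenate([[0.0], np.cumsum(t * t)])
    Sc = np.concatenate([[0.0], np.cumsum(c)])
    Stc = np.concatenate([[0.0], np.cumsum(t * c)])

    n = S0[hi] - S0[lo]
    st = St[hi] - St[lo]
    stt = Stt[hi] - Stt[lo]
    sc = Sc[hi] - Sc[lo]
    stc = Stc[hi] - Stc[lo]
    denom = n * stt - st * st
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * stc - st * sc) / denom

    rate = -slope * n_air / leaf_area
    rate = rate + chamber.leak_coefficient * (chamber.ambient_co2 - c) \
        * n_air / leaf_area
    ok = valid & (n >= 2) & (denom > 0)
    return RateSeries(time=t[ok], rate=rate[ok], window=window)


def estimate_leak(leak_trace: GasExchangeTrace, chamber: ChamberSpec):
    """First-order leak coefficient from a plant-free decay trace.

    Fits C(t) = ambient + (C0 - ambient) * exp(-k t). Returns ``(k, rmse)``;
    a non-decaying trace yields k = 0 with a warning.
    """
    t = leak_trace.time - leak_trace.time[0]
    c = leak_trace.co2
    amb = chamber.ambient_co2
    if c[0] <= amb or c[-1] >= c[0] - 1e-12:
        warnings.warn("trace does not decay toward ambient; returning k = 0")
        return 0.0, float(np.sqrt(np.mean((c - c[0]) ** 2)))

    def model(tt, k):
        return amb + (c[0] - amb) * np.exp(-k * tt)

    k0 = max(1e-9, -math.log(max((c[-1] - amb), 1e-9) / (c[0] - amb)) / t[-1])
    popt, _ = curve_fit(model, t, c, p0=[k0], bounds=(0.0, 1.0))
    k = float(popt[0])
    rmse = float(np.sqrt(np.mean((model(t, k) - c) ** 2)))
    return k, rmse


def simulate_drawdown(rate_model, chamber: ChamberSpec, c0: float,
                      duration: float, dt: float = 1.0) -> GasExchangeTrace:
    """Forward-simulate chamber CO2 under a canopy flux model.

    ``rate_model(C, t)`` returns whole-plant net CO2 uptake in umol s^-1
    (may invoke the full light/photosynthesis pipeline). Integrates
    dC/dt = (-flux(C, t) + k_leak * (ambient - C) * n) / n with classic
    fourth-order Runge-Kutta at fixed step ``dt``. Concentrations that would
    go negative are clipped to zero with a warning.
    """
    if c0 < 0 or dt <= 0 or duration <= 0:
        raise ValueError("c0 >= 0 and positive dt, duration required")
    n_air = air_moles(chamber)
    k = chamber.leak_coefficient
    amb = chamber.ambient_co2

    def dCdt(C, t):
        return (-rate_model(C, t) + k * (amb - C) * n_air) / n_air

    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    c = np.empty(n_steps + 1)
    c[0] = c0
    clipped = False
    for i in range(n_steps):
        ti, Ci = t[i], c[i]
        k1 = dCdt(Ci, ti)
        k2 = dCdt(Ci + 0.5 * dt * k1, ti + 0.5 * dt)
        k3 = dCdt(Ci + 0.5 * dt * k2, ti + 0.5 * dt)
        k4 = dCdt(Ci + dt * k3, ti + dt)
        nxt = Ci + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if nxt < 0.0:
            nxt = 0.0
            clipped = True
        c[i + 1] = nxt
    if clipped:
        warnings.warn("CO2 concentration clipped at zero during simulation")
    return GasExchangeTrace(time=t, co2=c)


# ----------------------------------------------------------------------------
# I/O (generic IRGA logger CSV: timestamp or seconds, co2_ppm)
# ----------------------------------------------------------------------------

def read_trace_csv(path) -> GasExchangeTrace:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("time", cols.get("timestamp", df.columns[0]))
    ccol = cols.get("co2_ppm", cols.get("co2", df.columns[1]))
    tv = df[tcol]
    try:
        t = tv.astype(float).to_numpy()
    except (TypeError, ValueError):
        ts = pd.to_datetime(tv)
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    return GasExchangeTrace(time=t, co2=df[ccol].to_numpy(float))


def write_rate_csv(series: RateSeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "rate": series.rate}).to_csv(
        path, index=False)
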