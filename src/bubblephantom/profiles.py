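"""Discretized ambient-pressure time courses (dive profiles).

Profiles store ABSOLUTE pressure as piecewise-linear breakpoints; every
constructor accepts ``gauge=True`` to interpret its pressure arguments as
gauge readings (one standard atmosphere is then added), because chamber
instrumentation reports gauge while the Young-Laplace balance needs
absolute pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ATMOSPHERE

#: Seawater density (kg m^-3) and gravity (m s^-2) for depth conversion.
RHO_SEAWATER = 1025.0
GRAVITY = 9.81


def depth_to_pressure(depth_m: float, rho: float = RHO_SEAWATER, g: float = GRAVITY) -> float:
    """Hydrostatic pressure increment (Pa) of a water column of ``depth_m`` metres."""
    return rho * g * depth_m


@dataclass(frozen=True)
class PressureProfile:
    """Piecewise-linear ambient pressure versus time.

    ``times`` strictly increasing starting at 0 (s); ``pressures`` >= 0 (Pa).
    """

    times: np.ndarray
    pressures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        if t.ndim != 1 or t.shape != p.shape or t.size < 2:
            raise ValueError("profile needs matching 1D times/pressures with >= 2 breakpoints")
        if t[0] != 0.0:
            raise ValueError("profile must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("pressures must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def initial_pressure(self) -> float:
        return float(self.pressures[0])

    @property
    def final_pressure(self) -> float:
        return float(self.pressures[-1])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "pressure_Pa": self.pressures}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "PressureProfile":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["time_s"].to_numpy(), df["pressure_Pa"].to_numpy())


def pressure_at(profile: PressureProfile, t, clamp: bool = False):
    """Ambient pressure at time ``t`` by linear interpolation (exact at breakpoints).

    Outside ``[0, duration]`` the value is an error unless ``clamp`` is set,
    in which case the endpoint value is held and a warning issued once per call.
    """
    t_arr = np.asarray(t, dtype=float)
    out_of_range = (t_arr < 0) | (t_arr > profile.duration)
    if np.any(out_of_range):
        if not clamp:
            raise ValueError(
                f"time {t!r} outside profile range [0, {profile.duration}]"
            )
        warnings.warn("time outside profile range; endpoint pressure held", stacklevel=2)
    out = np.interp(t_arr, profile.times, profile.pressures)
    return float(out) if out.ndim == 0 else out


def _maybe_gauge(p: float, gauge: bool) -> float:
    return p + ATMOSPHERE if gauge else p


def make_ramp_hold_ramp(
    P_surface: float,
    P_depth: float,
    compression_rate: float,
    hold_time: float,
    decompression_rate: float,
    gauge: bool = False,
) -> PressureProfile:
    """Compression ramp, hold at depth, decompression ramp back to the surface.

    Rates are positive Pa s^-1. ``hold_time = 0`` gives a triangular profile.
    """
    P_surface = _maybe_gauge(P_surface, gauge)
    P_depth = _maybe_gauge(P_depth, gauge)
    if not P_depth > P_surface >= 0:
        raise ValueError("need P_depth > P_surface >= 0")
    if compression_rate <= 0 or decompression_rate <= 0:
        raise ValueError("rates must be positive")
    if hold_time < 0:
        raise ValueError("hold_time must be non-negative")
    dP = P_depth - P_surface
    t_up = dP / compression_rate
    t_down = dP / decompression_rate
    if hold_time == 0:
        times = [0.0, t_up, t_up + t_down]
        pressures = [P_surface, P_depth, P_surface]
    else:
        times = [0.0, t_up, t_up + hold_time, t_up + hold_time + t_down]
        pressures = [P_surface, P_depth, P_depth, P_surface]
    return PressureProfile(np.array(times), np.array(pressures))


def make_oscillatory(
    P_min: float, P_max: float, period: float, cycles: int, gauge: bool = False
) -> PressureProfile:
    """Triangle-wave profile: ``cycles`` repetitions of P_min -> P_max -> P_min."""
    P_min = _maybe_gauge(P_min, gauge)
    P_max = _maybe_gauge(P_max, gauge)
    if not P_max > P_min >= 0:
        raise ValueError("need P_max > P_min >= 0")
    if period <= 0:
        raise ValueError("period must be positive")
    if cycles < 1:
        raise ValueError("need at least one cycle")
    times = [0.0]
    pressures = [P_min]
    for c in range(int(cycles)):
        times += [c * period + period / 2.0, (c + 1) * period]
        pressures += [P_max, P_min]
    return PressureProfile(np.array(times), np.array(pressures))


def make_linear_decompression(
    depth_m: float,
    duration: float,
    surface_pressure: float = ATMOSPHERE,
    rho: float = RHO_SEAWATER,
    g: float = GRAVITY,
) -> PressureProfile:
    """Linear ascent from ``depth_m`` of water to the surface over ``duration`` s."""
    if depth_m <= 0 or duration <= 0:
        raise ValueError("depth and duration must be positive")
    start = surface_pressure + depth_to_pressure(depth_m, rho, g)
    return PressureProfile(
        np.array([0.0, duration]), np.array([start, surface_pressure])
    )
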