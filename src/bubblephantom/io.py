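"""Configuration loading, result serialization and synthetic test fixtures.

Configurations are single TOML files whose numeric keys carry explicit unit
suffixes (``h_m``, ``gamma_N_per_m``, ``D_m2_per_s`` ...) so that the
psi-versus-Pa and cm^2-versus-m^2 pitfalls of the source literature cannot
recur in user inputs. All tabular output is plain CSV with '.' decimal
separators; manifests are JSON.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_TEMPERATURE, GasMixture, MaterialParams, air_mixture
from .diffusion import GridSpec
from .dynamics import SimulationConfig, SimulationResult
from .metrics import RadiusTimeSeries, growth_model
from .profiles import (
    PressureProfile,
    make_linear_decompression,
    make_oscillatory,
    make_ramp_hold_ramp,
)


class ConfigError(ValueError):
    """A configuration file is missing or malformed."""


def _require(table: dict, key: str, where: str):
    if key not in table:
        raise ConfigError(f"missing required field {key!r} in [{where}]")
    return table[key]


def _build_profile(table: dict) -> PressureProfile:
    kind = _require(table, "kind", "profile")
    gauge = bool(table.get("gauge", False))
    if kind == "ramp_hold_ramp":
        return make_ramp_hold_ramp(
            _require(table, "P_surface_Pa", "profile"),
            _require(table, "P_depth_Pa", "profile"),
            _require(table, "compression_rate_Pa_per_s", "profile"),
            _require(table, "hold_time_s", "profile"),
            _require(table, "decompression_rate_Pa_per_s", "profile"),
            gauge=gauge,
        )
    if kind == "oscillatory":
        return make_oscillatory(
            _require(table, "P_min_Pa", "profile"),
            _require(table, "P_max_Pa", "profile"),
            _require(table, "period_s", "profile"),
            int(_require(table, "cycles", "profile")),
            gauge=gauge,
        )
    if kind == "linear_decompression":
        return make_linear_decompression(
            _require(table, "depth_m", "profile"),
            _require(table, "duration_s", "profile"),
            surface_pressure=table.get("surface_pressure_Pa", 1.01325e5),
        )
    if kind == "breakpoints":
        return PressureProfile(
            np.asarray(_require(table, "times_s", "profile"), dtype=float),
            np.asarray(_require(table, "pressures_Pa", "profile"), dtype=float),
        )
    raise ConfigError(f"unknown profile kind {kind!r}")


def load_config(path) -> SimulationConfig:
    """Read and validate a TOML simulation configuration.

    Required: ``[grid] h_m, shape`` and a ``[profile]`` table. Everything
    else defaults to the documented values (air mixture, T = 310.15 K,
    surface-diffusivity factor 30, hyperelastic tissue response, one
    stabilized nucleus of radius h). Out-of-range physical parameters
    produce warnings, not errors.
    """
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:  # message carries line/column
            raise ConfigError(f"malformed config {path}: {err}") from err

    gtab = raw.get("grid") or {}
    if not gtab:
        raise ConfigError("missing required table [grid]")
    grid = GridSpec(
        h=float(_require(gtab, "h_m", "grid")),
        shape=tuple(int(n) for n in _require(gtab, "shape", "grid")),
        geometry=gtab.get("geometry", "box"),
        boundary=gtab.get("boundary", "dirichlet"),
    )

    mtab = raw.get("mixture") or {}
    mixture = air_mixture(
        L_N2=float(mtab.get("L_N2", 0.0436)),
        L_O2=float(mtab.get("L_O2", 0.02)),
        D=float(mtab.get("D_m2_per_s", 1.4e-9)),
        temperature=float(mtab.get("temperature_K", DEFAULT_TEMPERATURE)),
    )

    ptab = raw.get("material") or {}
    material = MaterialParams(
        gamma=float(ptab.get("gamma_N_per_m", 0.056)),
        mu=float(ptab.get("mu_Pa", 2.0e6)),
        M=float(ptab.get("M_Pa_per_m3", 5.0e16)),
        K=float(ptab.get("K_Pa", 2.2e9)),
        P0_ref=float(ptab.get("P0_ref_Pa", 1.01325e5)),
        surf_factor=float(ptab.get("surf_factor", 30.0)),
        surf_exponent=int(ptab.get("surf_exponent", 2)),
        elasticity_form=ptab.get("elasticity_form", "hyperelastic"),
    )

    if "profile" not in raw:
        raise ConfigError("missing required table [profile]")
    profile = _build_profile(raw["profile"])

    stab = raw.get("simulation") or {}
    placement = stab.get("placement")
    return SimulationConfig(
        grid=grid,
        mixture=mixture,
        material=material,
        profile=profile,
        n_bubbles=int(stab.get("n_bubbles", 1)),
        R_0=float(stab["R_0_m"]) if "R_0_m" in stab else None,
        seed=int(stab.get("seed", 0)),
        placement=[list(map(float, p)) for p in placement] if placement else None,
        initial_stabilized=bool(stab.get("initial_stabilized", True)),
        restabilize=bool(stab.get("restabilize", True)),
        coalescence=bool(stab.get("coalescence", True)),
        coupling=stab.get("coupling", "flux_sink"),
        t_end=float(stab["t_end_s"]) if "t_end_s" in stab else None,
        output_stride=int(stab.get("output_stride", 1)),
        safety=float(stab.get("safety", 0.9)),
    )


def write_timeseries(series: list[RadiusTimeSeries], path) -> None:
    """Tidy CSV (bubble_id, t_s, R_m, P_amb_Pa, event); lossless round trip."""
    if not series:
        raise ValueError("no radius-time series to write")
    frames = []
    for s in series:
        P = s.meta.get("P_amb")
        frames.append(
            pd.DataFrame(
                {
                    "bubble_id": s.meta.get("bubble_id", 0),
                    "t_s": s.t,
                    "R_m": s.R,
                    "P_amb_Pa": P if P is not None else np.nan,
                    "event": s.meta.get("event", ""),
                }
            )
        )
    # default float formatting is shortest-round-trip, hence lossless
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timeseries(path) -> list[RadiusTimeSeries]:
    """Inverse of :func:`write_timeseries`, grouped by bubble_id."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for bid, grp in df.groupby("bubble_id", sort=True):
        meta = {"bubble_id": int(bid)}
        if grp["P_amb_Pa"].notna().all():
            meta["P_amb"] = grp["P_amb_Pa"].to_numpy()
        out.append(RadiusTimeSeries(grp["t_s"].to_numpy(), grp["R_m"].to_numpy(), meta))
    return out


def generate_fixture_series(
    plateau: float,
    half_life: float,
    n: int = 200,
    noise_cv: float = 0.0,
    seed: int = 0,
    span_half_lives: float = 5.0,
) -> RadiusTimeSeries:
    """Synthetic radius-time curve from the one-phase association law.

    Samples ``n`` points on a uniform grid spanning ``span_half_lives``
    half-lives (>= 5 so the plateau is observed) with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``; reproducible
    from ``seed``. A stand-in for experimentally measured nucleated-bubble
    growth curves when exercising the regression stage.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    if span_half_lives < 5.0:
        raise ValueError("fixture must span at least 5 half-lives")
    t = np.linspace(0.0, span_half_lives * half_life, n)
    R = growth_model(t, plateau, half_life)
    if noise_cv:
        rng = np.random.default_rng(seed)
        R = R * (1.0 + noise_cv * rng.standard_normal(n))
    R = np.maximum(R, 0.0)
    return RadiusTimeSeries(t, R, {"plateau": plateau, "half_life": half_life, "seed": seed})


@dataclass
class RunManifest:
    """Reproducibility record: config echo, seed, timestep, grid, events."""

    config: dict
    seed: int
    dt: float
    grid_shape: list
    software_version: str = "bubblephantom 0.1.0"
    events: list = field(default_factory=list)

    @classmethod
    def from_result(cls, result: SimulationResult, config_echo: dict | None = None):
        m = result.manifest
        return cls(
            config=config_echo or {},
            seed=m["seed"],
            dt=m["dt"],
            grid_shape=m["grid_shape"],
            events=m["events"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
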