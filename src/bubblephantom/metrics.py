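"""Analysis of bubble radius-time curves: peak metrics, growth regression,
one-at-a-time sensitivity scans, and nucleation desk calculations."""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class RadiusTimeSeries:
    """One bubble's radius versus time (strictly increasing t, radii >= 0)."""

    t: np.ndarray
    R: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.shape != self.R.shape or self.t.ndim != 1:
            raise ValueError("t and R must be matching 1D arrays")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.R < 0):
            raise ValueError("radii must be non-negative")

    def __len__(self) -> int:
        return self.t.size

    def after(self, t0: float) -> "RadiusTimeSeries":
        """The sub-series with t >= t0, re-zeroed at t0 (for plateau fits)."""
        keep = self.t >= t0
        return RadiusTimeSeries(self.t[keep] - t0, self.R[keep], dict(self.meta))


@dataclass
class GrowthFit:
    """Result of the one-phase-association regression."""

    plateau: float
    half_life: float
    rss: float
    converged: bool
    baseline: float = 0.0


@dataclass
class SensitivityResult:
    parameter: str
    values: np.ndarray
    R_max: np.ndarray
    t_max: np.ndarray
    sensitivity_R: float | None
    sensitivity_t: float | None
    #: dimensionless elasticities |(x/metric) dmetric/dx| at the modal value,
    #: comparable across parameters
    elasticity_R: float | None = None
    elasticity_t: float | None = None


def max_radius_metrics(series: RadiusTimeSeries, refine: bool = False):
    """(R_max, t_max): the peak radius and the earliest time attaining it.

    With ``refine`` a parabola through the peak sample and its neighbours
    interpolates the true extremum, giving a t_max that varies continuously
    under parameter changes smaller than the recording step.
    """
    if len(series) == 0:
        raise ValueError("empty radius-time series")
    i = int(np.argmax(series.R))
    R_max, t_max = float(series.R[i]), float(series.t[i])
    if refine and 0 < i < len(series) - 1:
        t3, R3 = series.t[i - 1 : i + 2], series.R[i - 1 : i + 2]
        denom = (t3[0] - t3[1]) * (t3[0] - t3[2]) * (t3[1] - t3[2])
        if denom != 0:
            a = (
                t3[2] * (R3[1] - R3[0]) + t3[1] * (R3[0] - R3[2]) + t3[0] * (R3[2] - R3[1])
            ) / denom
            b = (
                t3[2] ** 2 * (R3[0] - R3[1])
                + t3[1] ** 2 * (R3[2] - R3[0])
                + t3[0] ** 2 * (R3[1] - R3[2])
            ) / denom
            if a < 0:
                tv = -b / (2 * a)
                if t3[0] <= tv <= t3[2]:
                    c = R3[0] - a * t3[0] ** 2 - b * t3[0]
                    t_max = float(tv)
                    R_max = float(a * tv**2 + b * tv + c)
    return R_max, t_max


def growth_model(t, plateau: float, half_life: float, baseline: float = 0.0):
    """One-phase association: R(t) = b + (plateau - b) * (1 - 2**(-t/half_life)).

    With ``baseline = 0`` this is the plateau/half-life exponential growth
    law used to summarize nucleated-bubble radius-time curves. The model is
    isolated here so an alternative regression family can be swapped in one
    place.
    """
    t = np.asarray(t, dtype=float)
    return baseline + (plateau - baseline) * (1.0 - 2.0 ** (-t / half_life))


def fit_growth_curve(series: RadiusTimeSeries, fix_baseline: bool = True) -> GrowthFit:
    """Least-squares fit of the one-phase association growth law.

    ``fix_baseline`` pins the curve's start to the first observed radius
    (zero for nucleated bubbles); the free parameters are always the plateau
    radius and the growth half-life. Multi-start initialization over the
    series span; an honest ``converged`` flag is reported instead of raising
    on degenerate input.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 points to fit the growth curve")
    if np.any(series.R < 0):
        raise ValueError("radii must be non-negative")
    t, R = series.t - series.t[0], series.R
    baseline = float(R[0]) if fix_baseline else 0.0
    span = float(t[-1] - t[0]) or 1.0
    if np.ptp(R) < 1e-9 * max(R.max(), 1e-300):
        # constant series: plateau is the constant, half-life unidentifiable
        return GrowthFit(
            plateau=float(R.mean()), half_life=math.nan,
            rss=float(((R - R.mean()) ** 2).sum()), converged=False,
            baseline=baseline,
        )

    def model(tt, plateau, half_life):
        return growth_model(tt, plateau, half_life, baseline)

    best = None
    for hl0 in (span / 10.0, span / 3.0, span):
        try:
            popt, _ = curve_fit(
                model, t, R,
                p0=[max(R.max(), 1e-12), hl0],
                bounds=([0.0, 1e-12], [np.inf, np.inf]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((model(t, *popt) - R) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return GrowthFit(math.nan, math.nan, math.inf, converged=False, baseline=baseline)
    (plateau, half_life), rss = best
    converged = bool(plateau > 0 and half_life > 0 and np.isfinite(rss))
    # half-life pushed far beyond the observation window is unidentifiable
    if half_life > 50.0 * span:
        converged = False
    return GrowthFit(float(plateau), float(half_life), rss, converged, baseline)


def critical_radius(P_ss: float, gamma: float) -> float:
    """Critical nucleation radius R_c = 2*gamma/P_ss (m).

    Nuclei larger than R_c grow under a tissue supersaturation P_ss (the
    excess of dissolved-gas tension over the ambient-equilibrium value);
    smaller nuclei dissolve.
    """
    if P_ss <= 0:
        raise ValueError("supersaturation must be positive (no energy barrier crossing defined)")
    if gamma <= 0:
        raise ValueError("surface tension must be positive")
    return 2.0 * gamma / P_ss


def surface_tension_share(R: float, gamma: float, P_amb: float, omega: float = 0.0) -> float:
    """Fraction of the internal bubble pressure contributed by surface tension:
    (2*gamma/R) / (P_amb + 2*gamma/R + omega)."""
    if R <= 0:
        raise ValueError("radius must be positive")
    laplace = 2.0 * gamma / R
    return laplace / (P_amb + laplace + omega)


_SCAN_PARAMS = ("D", "mu", "gamma", "LN2", "LO2")

#: plausible parameter ranges (outside them the scan warns)
_SCAN_RANGES = {
    "D": (1e-10, 2.7e-9),
    "mu": (0.0, 4e6),
    "gamma": (0.042, 0.07),
    "LN2": (0.005, 0.2),
    "LO2": (0.013, 0.027),
}


def _with_parameter(base_config, parameter: str, value: float):
    """A deep-copied config with one material/transport parameter replaced."""
    from .core import GasMixture, GasSpecies

    cfg = copy.deepcopy(base_config)
    if parameter == "mu":
        cfg.material.mu = value
    elif parameter == "gamma":
        cfg.material.gamma = value
    else:
        new_species = []
        for s in cfg.mixture.species:
            kw = dict(name=s.name, L=s.L, alpha=s.alpha, D_bulk=s.D_bulk, m_f=s.m_f)
            if parameter == "D":
                kw["D_bulk"] = value
            elif parameter == "LN2" and s.name == "N2":
                kw["L"] = value
            elif parameter == "LO2" and s.name == "O2":
                kw["L"] = value
            new_species.append(GasSpecies(**kw))
        cfg.mixture = GasMixture(tuple(new_species), cfg.mixture.temperature)
    return cfg


def sensitivity_scan(base_config, parameter: str, values) -> SensitivityResult:
    """One-at-a-time sensitivity of R_max and t_max to one material parameter.

    Runs the full simulation at each value (all other parameters held at the
    base config), extracts the peak metrics, and reports central-difference
    sensitivities Delta(metric)/Delta(parameter) at the middle (modal) value
    together with dimensionless elasticities for cross-parameter ranking.
    """
    import warnings as _warnings

    from .dynamics import run_simulation

    if parameter not in _SCAN_PARAMS:
        raise ValueError(f"parameter must be one of {_SCAN_PARAMS}, got {parameter!r}")
    values = np.asarray(values, dtype=float)
    lo, hi = _SCAN_RANGES[parameter]
    if np.any((values < lo) | (values > hi)):
        _warnings.warn(
            f"scan values for {parameter} outside the plausible range [{lo}, {hi}]",
            stacklevel=2,
        )
    R_max = np.empty(values.size)
    t_max = np.empty(values.size)
    for i, v in enumerate(values):
        cfg = _with_parameter(base_config, parameter, v)
        result = run_simulation(cfg)
        # metrics of the first (centred) bubble
        R_max[i], t_max[i] = max_radius_metrics(result.series[0], refine=True)
    if values.size >= 3:
        mid = values.size // 2
        dv = values[mid + 1] - values[mid - 1]
        sens_R = float((R_max[mid + 1] - R_max[mid - 1]) / dv)
        sens_t = float((t_max[mid + 1] - t_max[mid - 1]) / dv)
        elas_R = abs(sens_R) * values[mid] / R_max[mid] if R_max[mid] else None
        elas_t = abs(sens_t) * values[mid] / t_max[mid] if t_max[mid] else None
    else:
        sens_R = sens_t = elas_R = elas_t = None
    return SensitivityResult(
        parameter=parameter, values=values, R_max=R_max, t_max=t_max,
        sensitivity_R=sens_R, sensitivity_t=sens_t,
        elasticity_R=elas_R, elasticity_t=elas_t,
    )
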