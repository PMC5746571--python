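"""Bubble radius evolution, stabilized micronuclei, coalescence and the main loop.

Bubbles are Lagrangian spheres (fixed centre, continuous radius) living on
the Eulerian concentration grid. Each time step:

1. the ambient pressure is read from the dive profile,
2. phantom-edge Dirichlet values are refreshed (Henry's law at ambient),
3. each gas field takes one explicit diffusion step,
4. each bubble is updated - stabilized nuclei follow the no-flux Boyle
   rule, free bubbles exchange mass by Fick's first law across the bubble
   surface (with the reduced surface diffusivity D_surf) and their new
   radius solves the Young-Laplace / perfect-gas closure,
5. bubbles are re-rasterized onto the grid (dissolved gas at nodes engulfed
   by growth is displaced into the adjacent liquid ahead of the interface;
   nodes uncovered by shrinkage are refilled at the surface Henry
   concentration and the bubble debited, so the per-gas mass ledger stays
   closed),
6. contacting bubbles coalesce immediately into a single bubble carrying
   the summed gas mass.

The bubble-field exchange ("flux_sink" coupling, the default) removes from
the surface-adjacent liquid nodes exactly the mass the bubble gains, making
the dissolved + free gas ledger close to round-off; the alternative
"dirichlet" coupling instead injects the surface concentration into the
diffusion stencil as a missing-neighbour value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import (
    BOUNDARY, GAS, LIQUID, OUTSIDE,
    BubbleState, GasMixture, MaterialParams, SimulationState,
    equilibrium_concentration,
)
from .diffusion import (
    GridSpec, _gradient_weights, apply_edge_boundary, stable_timestep,
    step_diffusion, surface_adjacent_nodes,
)
from .elasticity import (
    ElasticityForm, boyle_equilibrium_radius, bubble_pressure, omega,
    omega_derivative,
)
from .metrics import RadiusTimeSeries
from .profiles import PressureProfile


class DomainContactError(RuntimeError):
    """A bubble has grown or merged into the phantom boundary."""


@dataclass(frozen=True)
class SurfaceDiffusionModel:
    """Reduced diffusivity across the bubble surface.

    D_surf(R_B) = (D_bulk / factor) * (R_0 / R_B)**exponent

    ``factor`` is the bulk-to-surface ratio at R_B = R_0 (fitted value 30);
    ``exponent`` sets the radius dependence. The default -2 makes D_surf
    grow with the bubble surface area (an adsorbed contaminant skin diluted
    as the interface expands); +2 gives the opposite dependence.
    """

    factor: float = 30.0
    exponent: int = -2

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("surface diffusivity cannot exceed the bulk value at R_0")


def surface_diffusion_coefficient(
    model: SurfaceDiffusionModel, D_bulk: float, R_B: float, R_0: float
) -> float:
    """D_surf in m^2 s^-1; equals D_bulk/factor at R_B = R_0 for any exponent."""
    if R_B <= 0 or R_0 <= 0:
        raise ValueError("radii must be positive")
    return (D_bulk / model.factor) * (R_0 / R_B) ** model.exponent


@dataclass
class SimulationConfig:
    """Everything needed to run (and re-run bit-identically) one simulation."""

    grid: GridSpec
    mixture: GasMixture
    material: MaterialParams
    profile: PressureProfile
    n_bubbles: int = 1
    R_0: float | None = None  # default: one grid spacing
    seed: int = 0
    placement: list | None = None  # explicit centres (m); None = random uniform
    initial_stabilized: bool = True
    restabilize: bool = True
    coalescence: bool = True
    coupling: str = "flux_sink"  # or "dirichlet"
    t_end: float | None = None  # default: profile duration
    output_stride: int = 1
    safety: float = 0.9

    def __post_init__(self) -> None:
        if self.R_0 is None:
            self.R_0 = self.grid.h
        if self.R_0 < self.grid.h:
            warnings.warn(
                f"initial radius {self.R_0} below one grid spacing {self.grid.h}; "
                "sub-grid bubbles use the nearest-node treatment",
                stacklevel=2,
            )
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be non-negative")
        if self.coupling not in ("flux_sink", "dirichlet"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")

    @property
    def surface_model(self) -> SurfaceDiffusionModel:
        return SurfaceDiffusionModel(
            factor=self.material.surf_factor, exponent=self.material.surf_exponent
        )


# ---------------------------------------------------------------------------
# Young-Laplace / perfect-gas closure
# ---------------------------------------------------------------------------

def gas_content(bubble_mass: np.ndarray, mixture: GasMixture) -> float:
    """sum_g m_g * alpha_g * T: the P*V content of the bubble (J = Pa m^3)."""
    return float(np.dot(bubble_mass, mixture.alphas) * mixture.temperature)


def masses_for_radius(
    R: float,
    P_amb: float,
    material: MaterialParams,
    mixture: GasMixture,
    R_0: float,
    fractions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gas masses of a bubble of radius R in mechanical equilibrium."""
    form = ElasticityForm.from_material(material)
    P_B = bubble_pressure(R, P_amb, material.gamma, form, R_0)
    V = 4.0 / 3.0 * math.pi * R**3
    f = mixture.fractions if fractions is None else np.asarray(fractions)
    return f * P_B * V / (mixture.alphas * mixture.temperature)


def radius_from_masses(
    mass: np.ndarray,
    P_amb: float,
    material: MaterialParams,
    mixture: GasMixture,
    R_0: float,
    R_guess: float | None = None,
) -> float:
    """Radius solving P_B(R) * (4 pi/3) R^3 = sum_g m_g alpha_g T.

    Root-found with a geometrically expanded bracket around the ideal-gas
    estimate; for the non-monotone tissue forms the smallest positive root
    is taken.
    """
    S = gas_content(np.asarray(mass, dtype=float), mixture)
    if S <= 0:
        return 0.0
    form = ElasticityForm.from_material(material)
    gamma = material.gamma
    c43 = 4.0 / 3.0 * math.pi

    def f(R: float) -> float:
        return (
            (P_amb + 2.0 * gamma / R + omega(form, R, R_0)) * c43 * R**3 - S
        )

    R_ideal = (3.0 * S / (4.0 * math.pi * max(P_amb, 1.0))) ** (1.0 / 3.0)
    monotone_form = material.elasticity_form in ("none", "bulk_modulus", "hyperelastic")
    if monotone_form and R_guess and R_guess > 0:
        # Newton fast path from the previous radius (closure is smooth and
        # monotone for these forms); falls through to bracketing on failure
        R = R_guess
        for _ in range(50):
            P_B = P_amb + 2.0 * gamma / R + omega(form, R, R_0)
            fval = P_B * c43 * R**3 - S
            dP = -2.0 * gamma / R**2 + omega_derivative(form, R, R_0)
            dfdR = c43 * (3.0 * R**2 * P_B + R**3 * dP)
            if dfdR <= 0:
                break
            step = fval / dfdR
            R_new = R - step
            if R_new <= 0:
                R_new = R / 2.0
            if abs(R_new - R) <= 1e-14 * R:
                return float(R_new)
            R = R_new
    lo = (R_guess or R_ideal) / 4.0
    hi = (R_guess or R_ideal) * 4.0
    for _ in range(12):
        if monotone_form:
            if f(lo) <= 0 <= f(hi):
                return float(brentq(f, lo, hi, xtol=1e-300, rtol=1e-14))
        else:
            grid = np.geomspace(lo, hi, 256)
            vals = (
                bubble_pressure(grid, P_amb, material.gamma, form, R_0)
                * (4.0 / 3.0) * math.pi * grid**3
                - S
            )
            idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            if idx.size:
                i = idx[0]
                return float(brentq(f, grid[i], grid[i + 1], xtol=1e-300, rtol=1e-14))
        lo /= 4.0
        hi *= 4.0
    raise RuntimeError(
        f"radius closure failed to bracket a root (content={S:.3e}, P_amb={P_amb:.3e})"
    )


def surface_concentration(bubble: BubbleState, mixture: GasMixture) -> np.ndarray:
    """Henry concentration at the inner bubble surface for each gas: L_g m_g / V."""
    V = bubble.volume
    if V <= 0:
        return np.zeros(len(mixture.species))
    L = np.array([s.L for s in mixture.species])
    return L * bubble.mass / V


# ---------------------------------------------------------------------------
# per-bubble update rules
# ---------------------------------------------------------------------------

def update_radius(
    bubble: BubbleState,
    gradients: np.ndarray,
    P_amb: float,
    material: MaterialParams,
    mixture: GasMixture,
    dt: float,
    restabilize: bool = True,
) -> BubbleState:
    """Advance a free bubble one step: Fick mass flux then the radius closure.

    ``gradients`` is the per-gas radial concentration gradient at the bubble
    surface (kg m^-4, positive = influx). dm_g = 4 pi R^2 D_surf^g grad_g dt.
    If the closure radius falls below R_0 and ``restabilize`` is set, the
    bubble re-enters the stabilized (no-flux) state at R_0.
    """
    if bubble.stabilized:
        raise ValueError("update_radius called on a stabilized bubble")
    if dt <= 0:
        raise ValueError("dt must be positive")
    model = SurfaceDiffusionModel(material.surf_factor, material.surf_exponent)
    area = 4.0 * math.pi * bubble.R_B**2
    D_surf = np.array(
        [
            surface_diffusion_coefficient(model, s.D_bulk, bubble.R_B, bubble.R_0)
            for s in mixture.species
        ]
    )
    dm = area * D_surf * np.asarray(gradients, dtype=float) * dt
    new_mass = np.maximum(bubble.mass + dm, 0.0)
    R_new = radius_from_masses(
        new_mass, P_amb, material, mixture, bubble.R_0, R_guess=bubble.R_B
    )
    bubble.mass = new_mass
    if R_new < bubble.R_0 and restabilize:
        bubble.R_B = bubble.R_0
        bubble.stabilized = True
        bubble.P_ref = P_amb
        bubble.mass = masses_for_radius(
            bubble.R_0, P_amb, material, mixture, bubble.R_0,
            fractions=_mass_fractions(bubble.mass, mixture),
        )
    else:
        bubble.R_B = R_new
    return bubble


def _mass_fractions(mass: np.ndarray, mixture: GasMixture) -> np.ndarray:
    """Mole fractions implied by the current per-gas masses (fallback: mixture).

    Partial pressures (hence mole fractions) are proportional to m_g * alpha_g.
    """
    p = mass * mixture.alphas
    total = p.sum()
    return p / total if total > 0 else mixture.fractions


def stabilized_nucleus_step(
    bubble: BubbleState,
    P_amb: float,
    P_amb_initial: float,
    material: MaterialParams,
    mixture: GasMixture,
) -> BubbleState:
    """One step of the stabilized-micronucleus rule (no mass flux).

    The nucleus radius follows Boyle's law from its reference state
    (R_0 at ``P_amb_initial``). Compression leaves it clamped at R_0 - the
    skin admits gas, so the reference pressure ratchets up to the maximum
    ambient pressure experienced and the trapped masses re-equilibrate.
    Once the Boyle radius exceeds R_0 the skin breaks: ``stabilized`` flips
    False and diffusive mass flux is enabled.
    """
    if not bubble.stabilized:
        raise ValueError("stabilized_nucleus_step called on a released bubble")
    if P_amb >= P_amb_initial:
        # compression: the Boyle radius cannot exceed R_0, skip the solve
        bubble.R_B = bubble.R_0
        if P_amb > bubble.P_ref:
            bubble.P_ref = P_amb
            bubble.mass = masses_for_radius(
                bubble.R_0, bubble.P_ref, material, mixture, bubble.R_0
            )
        return bubble
    form = ElasticityForm.from_material(material)
    R_boyle = boyle_equilibrium_radius(
        bubble.R_0, P_amb_initial, P_amb, material.gamma, form
    )
    if R_boyle > bubble.R_0:
        bubble.stabilized = False
        bubble.R_B = R_boyle
    else:
        bubble.R_B = bubble.R_0
        bubble.P_ref = max(P_amb_initial, P_amb)
        bubble.mass = masses_for_radius(
            bubble.R_0, bubble.P_ref, material, mixture, bubble.R_0
        )
    return bubble


# ---------------------------------------------------------------------------
# coalescence
# ---------------------------------------------------------------------------

def _check_containment(bubble: BubbleState, grid: GridSpec) -> None:
    ext = grid.extent
    c = bubble.center
    if grid.geometry == "box":
        wall = min(min(c[k], ext[k] - c[k]) for k in range(3))
    else:
        cx, cy = ext[0] / 2.0, ext[1] / 2.0
        radial = min(ext[0], ext[1]) / 2.0 - math.hypot(c[0] - cx, c[1] - cy)
        wall = min(radial, c[2], ext[2] - c[2])
    if bubble.R_B >= wall:
        raise DomainContactError(
            f"bubble {bubble.bubble_id} (R={bubble.R_B:.3e} m) overlaps the "
            f"phantom boundary (distance to wall {wall:.3e} m)"
        )


def detect_and_coalesce(
    bubbles: list[BubbleState],
    P_amb: float,
    material: MaterialParams,
    mixture: GasMixture,
    grid: GridSpec | None = None,
) -> list[BubbleState]:
    """Merge every contacting pair (centre distance < R_i + R_j) until stable.

    Per-gas masses add exactly; the merged centre is the mass-weighted
    centroid; the merged radius solves the Young-Laplace/gas closure for the
    summed content. A merged bubble overlapping the phantom boundary raises
    :class:`DomainContactError` (the paper's simulation-termination case).
    """
    out = [b for b in bubbles]
    merged_any = True
    while merged_any:
        merged_any = False
        n = len(out)
        for i in range(n):
            for j in range(i + 1, n):
                bi, bj = out[i], out[j]
                dist = float(np.linalg.norm(bi.center - bj.center))
                if dist < bi.R_B + bj.R_B:
                    mi, mj = bi.mass.sum(), bj.mass.sum()
                    center = (bi.center * mi + bj.center * mj) / (mi + mj)
                    mass = bi.mass + bj.mass
                    R_0 = max(bi.R_0, bj.R_0)
                    R = radius_from_masses(
                        mass, P_amb, material, mixture, R_0,
                        R_guess=(bi.R_B**3 + bj.R_B**3) ** (1.0 / 3.0),
                    )
                    merged = BubbleState(
                        center=center, R_B=R, R_0=R_0, mass=mass,
                        stabilized=False,
                        P_ref=max(bi.P_ref, bj.P_ref),
                        bubble_id=min(bi.bubble_id, bj.bubble_id),
                    )
                    if grid is not None:
                        _check_containment(merged, grid)
                    out = [b for k, b in enumerate(out) if k not in (i, j)]
                    out.append(merged)
                    merged_any = True
                    break
            if merged_any:
                break
    return out


# ---------------------------------------------------------------------------
# seeding and rasterization
# ---------------------------------------------------------------------------

def seed_bubbles(config: SimulationConfig, rng: np.random.Generator) -> list[BubbleState]:
    """Place ``n_bubbles`` stabilized nuclei of radius R_0 uniformly at random.

    Centres keep at least R_0 + h clear of the phantom boundary and bubbles
    may not overlap at seeding. Reproducible from the generator state.
    """
    grid, R_0 = config.grid, config.R_0
    margin = R_0 + grid.h
    ext = grid.extent
    if config.placement is not None:
        centers = [np.asarray(c, dtype=float) for c in config.placement]
        if len(centers) != config.n_bubbles:
            raise ValueError("placement list length must equal n_bubbles")
    else:
        lo = np.array([margin] * 3)
        hi = np.array(ext) - margin
        if np.any(hi <= lo):
            raise ValueError("phantom too small for the requested bubble size")
        centers = []
        attempts = 0
        max_attempts = 1000 * max(config.n_bubbles, 1)
        while len(centers) < config.n_bubbles:
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {config.n_bubbles} non-overlapping bubbles "
                    f"after {max_attempts} attempts"
                )
            attempts += 1
            c = rng.uniform(lo, hi)
            if grid.geometry == "cylinder":
                cx, cy = ext[0] / 2.0, ext[1] / 2.0
                if math.hypot(c[0] - cx, c[1] - cy) > min(ext[0], ext[1]) / 2.0 - margin:
                    continue
            if all(np.linalg.norm(c - c2) > 2 * R_0 + grid.h for c2 in centers):
                centers.append(c)
    P0 = config.profile.initial_pressure
    bubbles = []
    for k, c in enumerate(centers):
        mass = masses_for_radius(R_0, P0, config.material, config.mixture, R_0)
        bubbles.append(
            BubbleState(
                center=c, R_B=R_0, R_0=R_0, mass=mass,
                stabilized=config.initial_stabilized, P_ref=P0, bubble_id=k,
            )
        )
    return bubbles


def _rasterize(
    state: SimulationState,
    bubbles: list[BubbleState],
    grid: GridSpec,
    base_phase: np.ndarray,
    owner: np.ndarray,
    mixture: GasMixture,
) -> np.ndarray:
    """Flag gas nodes, with engulf/uncover mass bookkeeping against ``owner``.

    Returns the new owner array and updates ``state.phase`` and the
    concentration fields in place. Raises DomainContactError if a bubble
    claims a phantom-edge or outside node.
    """
    h3 = grid.h**3
    new_owner = np.full(grid.shape, -1, dtype=np.int32)
    xs, ys, zs = grid.node_centers()
    for b in bubbles:
        i0 = np.searchsorted(xs, b.center[0] - b.R_B) - 1
        i1 = np.searchsorted(xs, b.center[0] + b.R_B) + 1
        j0 = np.searchsorted(ys, b.center[1] - b.R_B) - 1
        j1 = np.searchsorted(ys, b.center[1] + b.R_B) + 1
        k0 = np.searchsorted(zs, b.center[2] - b.R_B) - 1
        k1 = np.searchsorted(zs, b.center[2] + b.R_B) + 1
        sl = (
            slice(max(i0, 0), min(i1, grid.shape[0])),
            slice(max(j0, 0), min(j1, grid.shape[1])),
            slice(max(k0, 0), min(k1, grid.shape[2])),
        )
        X, Y, Z = np.meshgrid(xs[sl[0]], ys[sl[1]], zs[sl[2]], indexing="ij")
        inside = (
            (X - b.center[0]) ** 2 + (Y - b.center[1]) ** 2 + (Z - b.center[2]) ** 2
            < b.R_B**2
        )
        local = new_owner[sl]
        claim = inside & (local == -1)
        local[claim] = b.bubble_id
        if not np.any(new_owner == b.bubble_id):
            # sub-grid bubble: claim the nearest in-domain node
            idx = np.unravel_index(
                np.argmin(
                    (xs[:, None, None] - b.center[0]) ** 2
                    + (ys[None, :, None] - b.center[1]) ** 2
                    + (zs[None, None, :] - b.center[2]) ** 2
                ),
                grid.shape,
            )
            new_owner[idx] = b.bubble_id
        if np.any((new_owner == b.bubble_id) & (base_phase != LIQUID)):
            raise DomainContactError(
                f"bubble {b.bubble_id} (R={b.R_B:.3e} m) has reached the phantom boundary"
            )
    by_id = {b.bubble_id: b for b in bubbles}
    phase = base_phase.copy()
    phase[new_owner >= 0] = GAS
    # engulfed nodes: the dissolved gas is displaced ahead of the moving
    # interface into the surface-adjacent liquid (solute rejection), keeping
    # the ledger closed without the grid-rate growth cascade that direct
    # absorption produces at high supersaturation
    engulfed = (new_owner >= 0) & (owner == -1)
    if np.any(engulfed):
        displaced: dict[int, np.ndarray] = {}
        for idx in np.argwhere(engulfed):
            bid = int(new_owner[tuple(idx)])
            amounts = displaced.setdefault(bid, np.zeros(len(mixture.species)))
            for g, s in enumerate(mixture.species):
                arr = state.conc[s.name]
                amounts[g] += arr[tuple(idx)] * h3
                arr[tuple(idx)] = 0.0
        for bid, amounts in displaced.items():
            nodes = surface_adjacent_nodes(new_owner, phase, bid)
            if nodes.shape[0] == 0:
                by_id[bid].mass += amounts  # enclosed bubble: nowhere to push
                continue
            for g, s in enumerate(mixture.species):
                state.conc[s.name][nodes[:, 0], nodes[:, 1], nodes[:, 2]] += (
                    amounts[g] / (nodes.shape[0] * h3)
                )
    # uncovered nodes: refill at the surface Henry concentration, debit the bubble
    uncovered = (owner >= 0) & (new_owner == -1)
    if np.any(uncovered):
        for idx in np.argwhere(uncovered):
            prev = by_id.get(int(owner[tuple(idx)]))
            if prev is None:
                continue
            C_s = surface_concentration(prev, mixture)
            for g, s in enumerate(mixture.species):
                take = min(C_s[g] * h3, prev.mass[g])
                state.conc[s.name][tuple(idx)] += take / h3
                prev.mass[g] -= take
    state.phase = phase
    return new_owner


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    series: list[RadiusTimeSeries]
    events: list[dict]
    manifest: dict
    state: SimulationState
    dt: float

    @property
    def terminated(self) -> bool:
        return any(e["event"] == "terminated" for e in self.events)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full coupled diffusion / bubble-growth simulation.

    The tissue starts fully saturated at the profile's initial pressure.
    Returns one radius-time series per seeded bubble (bubbles that coalesce
    stop being recorded; the surviving merged bubble continues under the
    smaller id) plus an event log and a reproducibility manifest.
    """
    grid, mixture, material, profile = (
        config.grid, config.mixture, config.material, config.profile,
    )
    rng = np.random.default_rng(config.seed)
    t_end = config.t_end if config.t_end is not None else profile.duration
    D_max = max(s.D_bulk for s in mixture.species)
    dt = stable_timestep(grid.h, D_max, config.safety)
    n_steps = int(math.ceil(t_end / dt))

    base_phase = grid.build_phase()
    P0 = profile.initial_pressure
    conc = {}
    for s in mixture.species:
        c0 = equilibrium_concentration(s, s.m_f * P0, mixture.temperature)
        arr = np.full(grid.shape, c0)
        arr[base_phase == OUTSIDE] = 0.0
        conc[s.name] = arr
    state = SimulationState(conc=conc, phase=base_phase.copy(), t=0.0)
    bubbles = seed_bubbles(config, rng)
    state.bubbles = bubbles
    owner = np.full(grid.shape, -1, dtype=np.int32)
    owner = _rasterize(state, bubbles, grid, base_phase, owner, mixture)

    events: list[dict] = []
    records: dict[int, dict[str, list]] = {
        b.bubble_id: {"t": [], "R": [], "P": []} for b in bubbles
    }
    model = config.surface_model
    h3 = grid.h**3

    def record(t: float, P: float) -> None:
        for b in bubbles:
            rec = records[b.bubble_id]
            rec["t"].append(t)
            rec["R"].append(b.R_B)
            rec["P"].append(P)

    record(0.0, P0)
    terminated = False
    for step in range(1, n_steps + 1):
        t = min(step * dt, t_end)
        P = np.interp(t, profile.times, profile.pressures)  # clamped beyond the end
        if grid.boundary == "dirichlet":
            apply_edge_boundary(state, mixture, P)
        # surface-value arrays only needed for the dirichlet coupling
        surf_conc = surf_D = None
        if config.coupling == "dirichlet":
            surf_conc = {s.name: np.zeros(grid.shape) for s in mixture.species}
            surf_D = {s.name: np.zeros(grid.shape) for s in mixture.species}
            for b in bubbles:
                if b.stabilized:
                    continue
                C_s = surface_concentration(b, mixture)
                mask = owner == b.bubble_id
                for g, s in enumerate(mixture.species):
                    surf_conc[s.name][mask] = C_s[g]
                    surf_D[s.name][mask] = surface_diffusion_coefficient(
                        model, s.D_bulk, b.R_B, b.R_0
                    )
        for s in mixture.species:
            step_diffusion(
                state, s, dt, grid,
                surf_conc=surf_conc[s.name] if surf_conc else None,
                surf_D=surf_D[s.name] if surf_D else None,
            )
        for b in bubbles:
            if b.stabilized:
                was = b.stabilized
                stabilized_nucleus_step(b, P, b.P_ref, material, mixture)
                if was and not b.stabilized:
                    events.append({"t": t, "event": "release", "bubble_id": b.bubble_id})
                continue
            nodes = surface_adjacent_nodes(owner, state.phase, b.bubble_id)
            if nodes.shape[0] == 0:
                raise RuntimeError(f"bubble {b.bubble_id} has no adjacent liquid nodes")
            C_s = surface_concentration(b, mixture)
            area = 4.0 * math.pi * b.R_B**2
            gradients = np.zeros(len(mixture.species))
            for g, s in enumerate(mixture.species):
                arr = state.conc[s.name]
                w, _ = _gradient_weights(arr, nodes, b, C_s[g], grid.h)
                grad = float(np.mean(w))
                if config.coupling == "flux_sink" and grad != 0.0:
                    D_surf = surface_diffusion_coefficient(model, s.D_bulk, b.R_B, b.R_0)
                    dm = area * D_surf * grad * dt
                    wsum = w.sum()
                    shares = w / wsum
                    deltas = dm * shares / h3
                    c_nodes = arr[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
                    # scale back if any node would be driven negative
                    over = deltas > c_nodes
                    if np.any(over):
                        with np.errstate(divide="ignore"):
                            factors = np.where(deltas > 0, c_nodes / np.maximum(deltas, 1e-300), np.inf)
                        scale = float(min(1.0, factors.min()))
                        dm *= scale
                        deltas = deltas * scale
                        grad *= scale
                    arr[nodes[:, 0], nodes[:, 1], nodes[:, 2]] = c_nodes - deltas
                gradients[g] = grad
            update_radius(
                b, gradients, P, material, mixture, dt, restabilize=config.restabilize
            )
        try:
            owner = _rasterize(state, bubbles, grid, base_phase, owner, mixture)
            if config.coalescence and len(bubbles) > 1:
                merged = detect_and_coalesce(bubbles, P, material, mixture, grid)
                if len(merged) != len(bubbles):
                    gone = {b.bubble_id for b in bubbles} - {b.bubble_id for b in merged}
                    events.append(
                        {"t": t, "event": "coalescence", "absorbed": sorted(gone)}
                    )
                    bubbles = merged
                    state.bubbles = bubbles
                    owner = _rasterize(state, bubbles, grid, base_phase, owner, mixture)
        except DomainContactError as err:
            events.append({"t": t, "event": "terminated", "reason": str(err)})
            terminated = True
        state.t = t
        if step % config.output_stride == 0 or step == n_steps or terminated:
            record(t, P)
        if terminated:
            break

    series = [
        RadiusTimeSeries(
            t=np.array(rec["t"]),
            R=np.array(rec["R"]),
            meta={"bubble_id": bid, "P_amb": np.array(rec["P"])},
        )
        for bid, rec in records.items()
        if len(rec["t"]) > 0
    ]
    manifest = {
        "seed": config.seed,
        "dt": dt,
        "n_steps": n_steps,
        "grid_shape": list(grid.shape),
        "h": grid.h,
        "t_end": t_end,
        "coupling": config.coupling,
        "elasticity_form": material.elasticity_form,
        "n_bubbles": config.n_bubbles,
        "events": events,
        "terminated": terminated,
    }
    return SimulationResult(series=series, events=events, manifest=manifest,
                            state=state, dt=dt)


def dissolved_mass(state: SimulationState, grid: GridSpec) -> dict[str, float]:
    """Total dissolved mass per gas (kg) over non-gas, in-domain nodes."""
    h3 = grid.h**3
    keep = (state.phase == LIQUID) | (state.phase == BOUNDARY)
    return {name: float(arr[keep].sum() * h3) for name, arr in state.conc.items()}


def total_gas_mass(
    state: SimulationState, grid: GridSpec, mixture: GasMixture
) -> np.ndarray:
    """Dissolved + free per-gas mass ledger (kg), ordered as the mixture."""
    diss = dissolved_mass(state, grid)
    out = np.array([diss[s.name] for s in mixture.species])
    for b in state.bubbles:
        out = out + b.mass
    return out
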