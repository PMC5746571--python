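"""Explicit finite-difference (FTCS) solver for dissolved-gas transport.

The tissue phantom is a 3D array of nodes with spacing ``h``; node centres
sit at ``(i + 1/2) * h``. Each node carries a phase flag:

* ``LIQUID``   - interior tissue, updated by the 7-point Laplacian,
* ``BOUNDARY`` - phantom edge, held at the Henry equilibrium with the
  ambient pressure (Dirichlet),
* ``GAS``      - inside a bubble, excluded from the stencil,
* ``OUTSIDE``  - outside the phantom (cylindrical domains inside a box
  grid); treated as a mirror (no-flux) neighbour.

Gas-phase neighbours are treated one of two ways, selected by the caller:
mirrored (no-flux; the bubble exchange is then applied as an explicit,
exactly mass-conserving sink - the default coupling in the simulation
loop), or as a Dirichlet neighbour carrying the bubble-surface Henry
concentration with the reduced surface diffusivity on that link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BOUNDARY, GAS, LIQUID, OUTSIDE, BubbleState, GasMixture, GasSpecies
from .core import SimulationState, equilibrium_concentration

_SHIFTS = [
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
]


@dataclass(frozen=True)
class GridSpec:
    """Node grid geometry: spacing ``h`` (m), node counts and domain shape.

    ``geometry`` is ``"box"`` (the whole array is phantom) or ``"cylinder"``
    (axis along z, diameter ``nx * h``, depth ``nz * h``; corner nodes are
    outside the domain). ``boundary`` selects Dirichlet phantom edges
    (``"dirichlet"``) or sealed no-flux faces (``"noflux"``).
    """

    h: float
    shape: tuple[int, int, int]
    geometry: str = "box"
    boundary: str = "dirichlet"

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("grid spacing must be positive")
        if len(self.shape) != 3 or any(n < 3 for n in self.shape):
            raise ValueError("grid needs at least 3 nodes per axis")
        if self.geometry not in ("box", "cylinder"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.boundary not in ("dirichlet", "noflux"):
            raise ValueError(f"unknown boundary condition {self.boundary!r}")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the node array (m)."""
        return tuple(n * self.h for n in self.shape)

    def node_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            (np.arange(n) + 0.5) * self.h for n in self.shape
        )

    def domain_mask(self) -> np.ndarray:
        """Boolean array: node lies inside the phantom."""
        nx, ny, nz = self.shape
        if self.geometry == "box":
            return np.ones(self.shape, dtype=bool)
        x, y, z = np.meshgrid(*self.node_centers(), indexing="ij")
        cx, cy = nx * self.h / 2.0, ny * self.h / 2.0
        radius = min(nx, ny) * self.h / 2.0
        return (x - cx) ** 2 + (y - cy) ** 2 <= radius**2

    def build_phase(self) -> np.ndarray:
        """Initial phase array (no bubbles rasterized yet)."""
        inside = self.domain_mask()
        phase = np.full(self.shape, OUTSIDE, dtype=np.int8)
        phase[inside] = LIQUID
        if self.boundary == "dirichlet":
            # a phantom-edge node is an inside node with a missing 6-neighbour
            pad = np.pad(inside, 1, constant_values=False)
            edge = np.zeros(self.shape, dtype=bool)
            for dx, dy, dz in _SHIFTS:
                nb = pad[
                    1 + dx : pad.shape[0] - 1 + dx,
                    1 + dy : pad.shape[1] - 1 + dy,
                    1 + dz : pad.shape[2] - 1 + dz,
                ]
                edge |= inside & ~nb
            phase[edge] = BOUNDARY
        return phase


def stable_timestep(h: float, D_max: float, safety: float = 1.0) -> float:
    """Largest stable explicit 3D FTCS step: safety * h^2 / (6 * D_max)."""
    if h <= 0 or D_max <= 0:
        raise ValueError("h and D_max must be positive")
    if not 0 < safety <= 1:
        raise ValueError("safety factor must lie in (0, 1]")
    return safety * h * h / (6.0 * D_max)


def apply_edge_boundary(
    state: SimulationState, mixture: GasMixture, P_amb: float
) -> SimulationState:
    """Set BOUNDARY nodes to the Henry equilibrium with the ambient pressure."""
    if P_amb < 0:
        raise ValueError("ambient pressure must be non-negative")
    edge = state.phase == BOUNDARY
    for species in mixture.species:
        state.conc[species.name][edge] = equilibrium_concentration(
            species, species.m_f * P_amb, mixture.temperature
        )
    return state


def _shift_slices(shift: tuple[int, int, int], shape: tuple[int, ...]):
    """Slices into a 1-padded array that read the ``shift``-neighbour of each node."""
    return tuple(
        slice(1 + d, n + 1 + d) for d, n in zip(shift, shape)
    )


def _shifted(arr: np.ndarray, shift: tuple[int, int, int], pad_mode: str, cval=0):
    if pad_mode == "edge":
        padded = np.pad(arr, 1, mode="edge")
    else:
        padded = np.pad(arr, 1, mode="constant", constant_values=cval)
    return padded[_shift_slices(shift, arr.shape)]


def step_diffusion(
    state: SimulationState,
    species: GasSpecies,
    dt: float,
    grid: GridSpec,
    surf_conc: np.ndarray | None = None,
    surf_D: np.ndarray | None = None,
) -> SimulationState:
    """One explicit 7-point-Laplacian update of one gas on the liquid nodes.

    Gas and outside-domain nodes are excluded from the stencil: outside
    neighbours mirror the centre value (no flux), and gas neighbours either
    mirror it too (default; bubble exchange applied separately) or, when
    ``surf_conc``/``surf_D`` arrays are given, act as Dirichlet neighbours
    at the bubble-surface concentration with the link diffusivity
    ``surf_D``. ``dt`` above the FTCS stability bound is an error.
    """
    D = species.D_bulk
    if dt > stable_timestep(grid.h, D) * (1.0 + 1e-12):
        raise ValueError(
            f"dt={dt} exceeds the FTCS stability bound "
            f"{stable_timestep(grid.h, D)} for D={D}"
        )
    conc = state.conc[species.name]
    phase = state.phase
    liquid = phase == LIQUID
    lap = np.zeros_like(conc)
    gas_flux = np.zeros_like(conc) if surf_conc is not None else None
    conc_p = np.pad(conc, 1, mode="edge")
    phase_p = np.pad(phase, 1, mode="constant", constant_values=OUTSIDE)
    if surf_conc is not None:
        surf_p = np.pad(surf_conc, 1, mode="edge")
        surfD_p = np.pad(surf_D, 1, mode="edge")
    for shift in _SHIFTS:
        sl = _shift_slices(shift, conc.shape)
        nb_conc = conc_p[sl]
        nb_phase = phase_p[sl]
        # mirror for outside neighbours, and for gas neighbours by default
        val = np.where((nb_phase == OUTSIDE) | (nb_phase == GAS), conc, nb_conc)
        lap += val - conc
        if surf_conc is not None:
            is_gas = nb_phase == GAS
            gas_flux += np.where(is_gas, surfD_p[sl] * (surf_p[sl] - conc), 0.0)
    update = (dt / grid.h**2) * (D * lap)
    if gas_flux is not None:
        update = update + (dt / grid.h**2) * gas_flux
    conc_new = conc + np.where(liquid, update, 0.0)
    np.maximum(conc_new, 0.0, out=conc_new)
    state.conc[species.name] = conc_new
    return state


def surface_adjacent_nodes(
    owner: np.ndarray, phase: np.ndarray, bubble_id: int
) -> np.ndarray:
    """Indices (n, 3) of liquid nodes 6-adjacent to nodes owned by a bubble."""
    mine_p = np.pad(owner == bubble_id, 1, mode="constant", constant_values=False)
    adj = np.zeros(owner.shape, dtype=bool)
    for shift in _SHIFTS:
        adj |= mine_p[_shift_slices(shift, owner.shape)]
    adj &= phase == LIQUID
    return np.argwhere(adj)


def boundary_gradient(
    state: SimulationState,
    bubble: BubbleState,
    C_surface: float,
    species: GasSpecies,
    grid: GridSpec,
    owner: np.ndarray,
    d_floor: float | None = None,
) -> float:
    """Radial concentration gradient (kg m^-4) at the bubble surface.

    Mean over surface-adjacent liquid nodes of (C_node - C_surface) / d,
    where d is the node-centre distance to the bubble surface (floored at
    h/2 to keep the estimate bounded when a node centre grazes the
    surface). Positive gradient means influx, i.e. growth.
    """
    nodes = surface_adjacent_nodes(owner, state.phase, bubble.bubble_id)
    if nodes.shape[0] == 0:
        raise ValueError(f"bubble {bubble.bubble_id} has no adjacent liquid nodes")
    w, _ = _gradient_weights(
        state.conc[species.name], nodes, bubble, C_surface, grid.h, d_floor
    )
    return float(np.mean(w))


def _gradient_weights(
    conc: np.ndarray,
    nodes: np.ndarray,
    bubble: BubbleState,
    C_surface: float,
    h: float,
    d_floor: float | None = None,
):
    """Per-node driving terms (C_i - C_s)/d_i and the node distances."""
    if d_floor is None:
        d_floor = h / 2.0
    centers = (nodes + 0.5) * h
    d = np.linalg.norm(centers - bubble.center, axis=1) - bubble.R_B
    d = np.maximum(d, d_floor)
    c_vals = conc[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
    return (c_vals - C_surface) / d, d
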