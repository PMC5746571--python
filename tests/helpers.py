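"""Shared oracles for the diffusion tests: 1D slab analytic solution."""

import math

import numpy as np

from bubblephantom import GridSpec, SimulationState
from bubblephantom.core import BOUNDARY, LIQUID, GasSpecies
from bubblephantom.core import ALPHA_N2
from bubblephantom.diffusion import stable_timestep, step_diffusion


def slab_series_solution(xi: np.ndarray, t: float, L: float, D: float, C0: float,
                         n_terms: int = 80) -> np.ndarray:
    """Dissolved concentration in a 1D slab of length L with C(0)=C0, C(L)=0
    and a step initial profile (C0 on the left half).

    Steady state plus Fourier sine series; the step's sine coefficients are
    b_k = -(2 C0 / (k pi)) cos(k pi / 2) (zero for odd k).
    """
    out = C0 * (1.0 - xi / L)
    for k in range(1, n_terms + 1):
        b_k = -(2.0 * C0 / (k * math.pi)) * math.cos(k * math.pi / 2.0)
        if b_k == 0.0:
            continue
        out = out + b_k * np.sin(k * math.pi * xi / L) * math.exp(
            -D * (k * math.pi / L) ** 2 * t
        )
    return out


def run_slab(n_nodes: int, L_eff: float, D: float, t_final: float, C0: float = 1.0):
    """Explicit FTCS solution of the slab problem on an (n, 3, 3) grid.

    Returns (numeric profile, analytic profile) at the interior nodes.
    The x-end node layers are Dirichlet; the y/z array edges act as no-flux
    mirrors so the field stays one-dimensional.
    """
    h = L_eff / (n_nodes - 1)
    grid = GridSpec(h=h, shape=(n_nodes, 3, 3), boundary="noflux")
    species = GasSpecies("N2", L=0.014, alpha=ALPHA_N2, D_bulk=D, m_f=1.0)

    phase = np.full(grid.shape, LIQUID, dtype=np.int8)
    phase[0], phase[-1] = BOUNDARY, BOUNDARY
    x = (np.arange(n_nodes) + 0.5) * h
    xi = x - x[0]
    init = np.where(xi < L_eff / 2.0, C0, 0.0)
    mid = np.isclose(xi, L_eff / 2.0)
    init[mid] = C0 / 2.0  # symmetric sampling of the jump
    init[-1] = 0.0

    conc = np.repeat(init[:, None, None], 3, axis=1).repeat(3, axis=2)
    state = SimulationState(conc={"N2": conc}, phase=phase)
    n_steps = int(math.ceil(t_final / stable_timestep(h, D, safety=0.9)))
    dt = t_final / n_steps
    for _ in range(n_steps):
        step_diffusion(state, species, dt, grid)
    numeric = state.conc["N2"][1:-1, 1, 1]
    analytic = slab_series_solution(xi[1:-1], t_final, L_eff, D, C0)
    return numeric, analytic


def slab_error(n_nodes: int, L_eff: float = 1.6e-3, D: float = 1.4e-9,
               t_final: float = 146.0) -> float:
    numeric, analytic = run_slab(n_nodes, L_eff, D, t_final)
    return float(np.max(np.abs(numeric - analytic)))
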