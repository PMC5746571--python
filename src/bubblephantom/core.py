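"""Domain types and gas-law primitives shared by every stage of the simulator.

Unit conventions (used everywhere in this package):

* pressures in Pa (absolute), radii/lengths in m, time in s,
* dissolved-gas concentrations in kg m^-3,
* specific gas constants ``alpha`` in J kg^-1 K^-1 (i.e. R/M per gas).

Gas solubility follows Henry's law expressed through the dimensionless
Ostwald coefficient L: the dissolved concentration in equilibrium with a
partial pressure ``pp`` at absolute temperature ``T`` is

    C = L * pp / (alpha * T)

``pp / (alpha * T)`` is the density the free gas would have at that partial
pressure, and L is the equilibrium volume-ratio of dissolved gas to liquid.
Parameter tables that quote a "specific gas constant" in kJ kg^-1 store the
temperature-absorbed product ``alpha * T`` (at 37 C: 92.07 kJ/kg for N2,
80.6 kJ/kg for O2); dividing by T = 310.15 K recovers the values used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618
#: Default absolute temperature: 37 C incubation, K.
DEFAULT_TEMPERATURE = 310.15
#: One standard atmosphere, Pa (used when converting gauge pressures).
ATMOSPHERE = 1.01325e5

#: Specific gas constant of N2 (R/M), J kg^-1 K^-1.
ALPHA_N2 = R_GAS / 0.0280134
#: Specific gas constant of O2, J kg^-1 K^-1.
ALPHA_O2 = R_GAS / 0.0319988

#: Surface-tension range (N/m) reported for soft tissue phantoms; values
#: outside it are accepted with a warning.
GAMMA_RANGE = (0.042, 0.07)

# phase codes for the 3D node grid
LIQUID = 0
GAS = 1
OUTSIDE = 2
BOUNDARY = 3  # phantom edge node held at the Henry equilibrium value


class ParameterRangeWarning(UserWarning):
    """A physical parameter lies outside its tabulated plausible range."""


@dataclass(frozen=True)
class GasSpecies:
    """Physical constants of one gas in the breathing mixture.

    Parameters
    ----------
    name : str
    L : float
        Ostwald solubility coefficient (dimensionless, > 0).
    alpha : float
        Specific gas constant R/M in J kg^-1 K^-1.
    D_bulk : float
        Diffusion coefficient in the bulk tissue phantom, m^2 s^-1.
    m_f : float
        Mole fraction in the breathing gas, in [0, 1].
    """

    name: str
    L: float
    alpha: float
    D_bulk: float
    m_f: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"Ostwald coefficient must be positive, got {self.L}")
        if not self.alpha > 0:
            raise ValueError(f"specific gas constant must be positive, got {self.alpha}")
        if not self.D_bulk > 0:
            raise ValueError(f"diffusion coefficient must be positive, got {self.D_bulk}")
        if not 0.0 <= self.m_f <= 1.0:
            raise ValueError(f"mole fraction must lie in [0, 1], got {self.m_f}")


@dataclass(frozen=True)
class GasMixture:
    """An ordered collection of gas species plus the (fixed) temperature."""

    species: tuple[GasSpecies, ...]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        total = sum(s.m_f for s in self.species)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mole fractions must sum to 1, got {total!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([s.m_f for s in self.species])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([s.alpha for s in self.species])


def air_mixture(
    L_N2: float = 0.0436,
    L_O2: float = 0.02,
    D: float = 1.4e-9,
    temperature: float = DEFAULT_TEMPERATURE,
) -> GasMixture:
    """A 0.2 : 0.8 O2 : N2 breathing-air mixture.

    Defaults are the modal sensitivity-baseline values; dive-profile and
    oscillatory experiments use the fitted collagen-gel values
    (``L_N2=0.145, L_O2=0.027, D=2.5e-9``).
    """
    return GasMixture(
        species=(
            GasSpecies("N2", L=L_N2, alpha=ALPHA_N2, D_bulk=D, m_f=0.8),
            GasSpecies("O2", L=L_O2, alpha=ALPHA_O2, D_bulk=D, m_f=0.2),
        ),
        temperature=temperature,
    )


@dataclass
class MaterialParams:
    """Mechanical and transport properties of the tissue phantom.

    ``M`` is the bulk-modulus elasticity parameter K/V_aff in Pa m^-3
    (note: SI, not Pa um^-3); ``P0_ref`` is the ambient pressure defining
    the stress-free reference configuration for the reference-configuration
    elasticity form. ``surf_factor``/``surf_exponent`` parametrize the
    reduced bubble-surface diffusivity
    D_surf = (D_bulk / surf_factor) * (R_0 / R_B)**surf_exponent;
    the default exponent -2 scales D_surf with the bubble surface area.
    """

    gamma: float = 0.056
    mu: float = 2.0e6
    M: float = 5.0e16
    K: float = 2.2e9
    P0_ref: float = ATMOSPHERE
    surf_factor: float = 30.0
    surf_exponent: int = -2
    elasticity_form: str = "hyperelastic"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("shear modulus must be non-negative")
        if self.surf_factor < 1:
            raise ValueError("surf_factor must be >= 1 (surface no more permeable than bulk)")
        if not GAMMA_RANGE[0] <= self.gamma <= GAMMA_RANGE[1]:
            warnings.warn(
                f"surface tension {self.gamma} N/m outside the tabulated "
                f"range {GAMMA_RANGE[0]}-{GAMMA_RANGE[1]} N/m",
                ParameterRangeWarning,
                stacklevel=2,
            )


@dataclass
class BubbleState:
    """One spherical bubble tracked over the Eulerian grid.

    ``mass`` holds one entry per gas species (kg), ordered as the mixture.
    ``stabilized`` is True while the no-flux micronucleus rule applies;
    ``P_ref`` is the ambient pressure at which the stabilized nucleus was
    last equilibrated (it tracks the maximum pressure experienced, so a
    nucleus compressed at depth releases on the subsequent decompression).
    """

    center: np.ndarray
    R_B: float
    R_0: float
    mass: np.ndarray
    stabilized: bool = True
    P_ref: float = ATMOSPHERE
    bubble_id: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.R_B < 0:
            raise ValueError("bubble radius must be non-negative")
        if np.any(self.mass < 0):
            raise ValueError("bubble gas masses must be non-negative")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.R_B**3


@dataclass
class SimulationState:
    """Concentration fields, node phase flags, bubbles and the clock."""

    conc: dict[str, np.ndarray]
    phase: np.ndarray
    bubbles: list[BubbleState] = field(default_factory=list)
    t: float = 0.0

    def __post_init__(self) -> None:
        for name, arr in self.conc.items():
            if arr.shape != self.phase.shape:
                raise ValueError(f"conc[{name!r}] shape {arr.shape} != phase shape {self.phase.shape}")

    @property
    def C_tot(self) -> np.ndarray:
        """Total dissolved gas concentration (sum over species), kg m^-3."""
        return sum(self.conc.values())


def equilibrium_concentration(species: GasSpecies, pp: float, T: float = DEFAULT_TEMPERATURE):
    """Dissolved concentration (kg m^-3) in equilibrium with partial pressure ``pp``.

    Henry's law through the Ostwald coefficient: C = L * pp / (alpha * T).
    Accepts scalar or array ``pp``.
    """
    pp = np.asarray(pp, dtype=float)
    if np.any(pp < 0):
        raise ValueError("partial pressure must be non-negative")
    if not T > 0:
        raise ValueError("temperature must be positive")
    out = species.L * pp / (species.alpha * T)
    return float(out) if out.ndim == 0 else out


def partial_pressure_from_concentration(
    species: GasSpecies, C: float, T: float = DEFAULT_TEMPERATURE
) -> float:
    """Inverse of :func:`equilibrium_concentration`: pp = C * alpha * T / L."""
    if np.any(np.asarray(C) < 0):
        raise ValueError("concentration must be non-negative")
    if not T > 0:
        raise ValueError("temperature must be positive")
    return C * species.alpha * T / species.L


def partial_pressures(P_amb: float, mixture: GasMixture) -> np.ndarray:
    """Per-gas partial pressures (Pa) of the breathing mixture at ``P_amb``."""
    if P_amb < 0:
        raise ValueError("ambient pressure must be non-negative")
    return mixture.fractions * P_amb
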