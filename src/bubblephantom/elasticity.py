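"""Tissue-elasticity response, Young-Laplace pressure and Boyle equilibria.

The pressure a deformed tissue exerts on a spherical bubble is written as a
term Omega(R_B) added to the Young-Laplace balance

    P_B = P_amb + 2*gamma/R_B + Omega(R_B).

Four forms of Omega are implemented, spanning the decompression-modelling
literature:

``none``
    Omega = 0 (fluid-like surroundings).
``bulk_modulus``
    Omega = M * (4*pi/3) * (R_B^3 - R_0^3), with M = K / V_aff the tissue
    bulk modulus over the affected volume. Widely used empirically; grows
    as the displaced volume, so it restricts large bubbles most.
``continuity_displacement``
    Omega = -(4*mu/3) * (1 - (R_0/R_B)^3), the small-shear-modulus
    (mu << K) linear-elastic result obtained by enforcing continuity of
    displacement at the gas-liquid interface. Persistently negative for a
    growing bubble, i.e. the tissue *assists* growth; for mu large compared
    with the final ambient pressure no equilibrium exists at all (the Boyle
    solver then reports a bracketing failure).
``reference_configuration``
    Omega = 4*mu * R_0^2 * (R_B - R_0) / R_B^3, the incompressible
    linear-elastic cavity solution with displacements measured from a
    stress-free reference configuration (bubble at R_0 under ambient
    pressure P0_ref). Zero at the reference state, positive resistance to
    initial growth.
``hyperelastic``
    Omega = (mu/2) * (5 - 4*(R_0/R_B) - (R_0/R_B)^4), the incompressible
    neo-Hookean (hyperelastic strain-energy) cavitation result. Zero at
    R_0, monotone increasing, finite asymptote 5*mu/2 as R_B -> inf. This
    is the default form for all simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import MaterialParams

FORMS = (
    "none",
    "bulk_modulus",
    "continuity_displacement",
    "reference_configuration",
    "hyperelastic",
)

# params each form needs, beyond R_0
_REQUIRED = {
    "none": (),
    "bulk_modulus": ("M",),
    "continuity_displacement": ("K", "mu"),
    "reference_configuration": ("mu", "P0_ref"),
    "hyperelastic": ("mu",),
}


@dataclass(frozen=True)
class ElasticityForm:
    """A tissue-response law plus the material parameters it reads."""

    kind: str
    M: float | None = None
    K: float | None = None
    mu: float | None = None
    P0_ref: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FORMS:
            raise ValueError(f"unknown elasticity form {self.kind!r}; choose from {FORMS}")
        for name in _REQUIRED[self.kind]:
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ValueError(
                    f"elasticity form {self.kind!r} requires finite parameter {name!r}"
                )
        if self.kind == "continuity_displacement" and self.mu is not None and self.K:
            if self.mu > 0.01 * self.K:
                warnings.warn(
                    "continuity-of-displacement form is only valid for mu << K",
                    stacklevel=2,
                )

    @classmethod
    def from_material(cls, material: MaterialParams, kind: str | None = None) -> "ElasticityForm":
        return cls(
            kind=kind or material.elasticity_form,
            M=material.M,
            K=material.K,
            mu=material.mu,
            P0_ref=material.P0_ref,
        )


def omega(form: ElasticityForm, R_B, R_0):
    """Tissue pressure term Omega(R_B) in Pa for the selected form.

    Accepts scalar or array ``R_B``.
    """
    R_B = np.asarray(R_B, dtype=float)
    if np.any(R_B <= 0) or R_0 <= 0:
        raise ValueError("radii must be positive")
    x = R_0 / R_B
    if form.kind == "none":
        out = np.zeros_like(R_B)
    elif form.kind == "bulk_modulus":
        out = form.M * (4.0 * np.pi / 3.0) * (R_B**3 - R_0**3)
    elif form.kind == "continuity_displacement":
        out = -(4.0 * form.mu / 3.0) * (1.0 - x**3)
    elif form.kind == "reference_configuration":
        out = 4.0 * form.mu * R_0**2 * (R_B - R_0) / R_B**3
    elif form.kind == "hyperelastic":
        out = 0.5 * form.mu * (5.0 - 4.0 * x - x**4)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(form.kind)
    return float(out) if out.ndim == 0 else out


def omega_derivative(form: ElasticityForm, R_B: float, R_0: float) -> float:
    """dOmega/dR_B (Pa m^-1), used by Newton steps in the radius closure."""
    if R_B <= 0 or R_0 <= 0:
        raise ValueError("radii must be positive")
    if form.kind == "none":
        return 0.0
    if form.kind == "bulk_modulus":
        return form.M * 4.0 * np.pi * R_B**2
    if form.kind == "continuity_displacement":
        return -4.0 * form.mu * R_0**3 / R_B**4
    if form.kind == "reference_configuration":
        return 4.0 * form.mu * R_0**2 * (3.0 * R_0 - 2.0 * R_B) / R_B**4
    # hyperelastic
    x = R_0 / R_B
    return 0.5 * form.mu * (4.0 * x / R_B + 4.0 * x**4 / R_B)


def bubble_pressure(R_B, P_amb: float, gamma: float, form: ElasticityForm, R_0: float):
    """Young-Laplace internal bubble pressure P_B = P_amb + 2*gamma/R_B + Omega(R_B)."""
    R_B = np.asarray(R_B, dtype=float)
    if np.any(R_B <= 0):
        raise ValueError("bubble radius must be positive")
    out = P_amb + 2.0 * gamma / R_B + omega(form, R_B, R_0)
    return float(out) if out.ndim == 0 else out


def boyle_equilibrium_radius(
    R_0: float,
    P_initial: float,
    P_final: float,
    gamma: float,
    form: ElasticityForm,
) -> float:
    """Equilibrium radius after a pressure change with no mass transfer.

    Solves P_B(R) * R^3 = P_B(R_0) * R_0^3 (isothermal Boyle's law, with the
    Young-Laplace/tissue closure on both sides). Only the branch the bubble
    can actually reach is searched - radii above R_0 on decompression, below
    on compression - so a persistently assisting tissue term that admits no
    finite equilibrium raises instead of returning a spurious shrinkage
    root. A geometric scan locates sign changes; the smallest positive root
    is returned, with a warning if the pressure-radius map admits several.
    """
    if not (P_initial > 0 and P_final > 0 and R_0 > 0):
        raise ValueError("pressures and initial radius must be positive")
    if P_final == P_initial:
        return float(R_0)
    target = bubble_pressure(R_0, P_initial, gamma, form, R_0) * R_0**3

    def f(R: float) -> float:
        return bubble_pressure(R, P_final, gamma, form, R_0) * R**3 - target

    ratio = (max(P_initial, P_final) / min(P_initial, P_final)) ** (1.0 / 3.0)
    decompression = P_final < P_initial
    if decompression:
        lo, hi = R_0, R_0 * ratio * 2.0
    else:
        lo, hi = R_0 / ratio / 2.0, R_0
    for _ in range(8):
        grid = np.geomspace(lo, hi, 512)
        vals = bubble_pressure(grid, P_final, gamma, form, R_0) * grid**3 - target
        sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if sign_changes.size:
            break
        if decompression:
            hi *= 4.0
        else:
            lo /= 4.0
    else:
        raise ValueError(
            f"no Boyle equilibrium: no sign change in bracket [{lo:.3e}, {hi:.3e}] m "
            f"for form {form.kind!r} (R_0={R_0:.3e}, {P_initial:.3e}->{P_final:.3e} Pa)"
        )
    if sign_changes.size > 1:
        warnings.warn(
            f"multiple Boyle equilibria for form {form.kind!r}; "
            "returning the smallest positive root",
            stacklevel=2,
        )
    i = sign_changes[0]
    if vals[i] == 0.0:
        return float(grid[i])
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-300, rtol=1e-14))


def laplace_curve(
    form: ElasticityForm, gamma: float, mu: float, R_0: float, radii
) -> np.ndarray:
    """P_B - P_amb = 2*gamma/R + Omega(R) over a radius grid.

    Used to map out the surface-tension- versus elasticity-dominated regimes
    of the dimensionless group gamma / (mu * R_0). ``mu`` overrides the
    form's shear modulus so parameter sweeps need not rebuild the form.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if form.kind in ("hyperelastic", "continuity_displacement", "reference_configuration"):
        form = ElasticityForm(kind=form.kind, M=form.M, K=form.K, mu=mu, P0_ref=form.P0_ref)
    return 2.0 * gamma / radii + omega(form, radii, R_0)
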