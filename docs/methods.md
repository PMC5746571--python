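# Methods

This note documents the model, its numerical treatment, the parameter
choices and their rationale, what the synthetic inputs do and do not
emulate, and the known limitations. It states no empirical result that the
test suite does not itself compute.

## Physical model

**Gas transport.** Each gas (O₂, N₂) diffuses independently through the
phantom, ∂C/∂t = D∇²C, with no perfusion, advection or metabolism. At the
phantom edge and at bubble surfaces the dissolved concentration is the
Henry/Ostwald equilibrium C = L·p/(αT): p is the relevant partial pressure
(the ambient mole-fraction split at the edge, the internal bubble partial
pressure at a bubble surface), L the dimensionless Ostwald solubility, α
the specific gas constant R/M in J kg⁻¹ K⁻¹, and T the absolute
temperature. Temperature is fixed (310.15 K, the 37 °C incubation value;
configurable), so parameter tables quoting a "specific gas constant" in
kJ kg⁻¹ are read as the temperature-absorbed product αT: 92.07 kJ kg⁻¹
(N₂) and 80.6 kJ kg⁻¹ (O₂) at 37 °C. Concentrations are kg m⁻³, pressures
Pa (absolute), radii m throughout.

**Bubble mechanics.** A bubble's internal pressure obeys the Young–Laplace
balance P_B = P_amb + 2γ/R_B + Ω(R_B). Five tissue-response laws Ω are
implemented:

| kind | Ω(R_B) | parameters |
|---|---|---|
| none | 0 | — |
| bulk_modulus | M·(4π/3)(R_B³ − R₀³) | M = K/V_aff |
| continuity_displacement | −(4μ/3)(1 − (R₀/R_B)³) | μ (valid for μ ≪ K) |
| reference_configuration | 4μR₀²(R_B − R₀)/R_B³ | μ, reference at (R₀, P₀) |
| hyperelastic (default) | (μ/2)(5 − 4(R₀/R_B) − (R₀/R_B)⁴) | μ |

The hyperelastic form is the incompressible neo-Hookean cavitation result:
zero at the reference radius, monotone, with the finite asymptote 5μ/2 —
so a stiff medium caps bubble growth at the strain where Ω matches the
available supersaturation. The continuity-of-displacement form is
persistently negative (the tissue *assists* growth); when μ exceeds ~¾ of
the final ambient pressure it admits no finite Boyle equilibrium at all,
which the equilibrium solver reports as a bracketing failure rather than
returning the spurious shrinkage root that exists on the unreachable
branch below R₀.

**Mass exchange.** dm_g/dt = 4πR_B²·D_surf^g·(∂C_g/∂r)|_surface, with the
surface gradient estimated from the surface-adjacent liquid nodes (below)
and the surface concentration from Henry's law at the internal partial
pressures (C_s,g = L_g·m_g/V_B). The surface diffusivity is reduced
relative to the bulk and scales with the bubble's surface area,

    D_surf = (D_bulk / 30) · (R_B / R₀)² ,

modelling an adsorbed contaminant skin that dilutes as the interface
expands. The factor 30 and the area scaling are adopted as defaults from
fits of this model family to collagen-gel observations; both the factor
and the exponent (±2) are configurable (`MaterialParams.surf_factor`,
`surf_exponent`). The area scaling is what makes the plateau radius depend
nonlinearly on the initial radius: with the opposite exponent the area
factor in the flux cancels exactly and the plateau becomes linear in R₀.

**Radius closure.** After each mass update the radius solves
P_B(R)·(4π/3)R³ = Σ_g m_g α_g T. For the monotone forms a Newton iteration
from the previous radius (analytic dΩ/dR) is used, falling back to a
bracketed Brent solve; the non-monotone forms are scanned geometrically
and the smallest positive root taken.

**Stabilized micronuclei.** Seeded bubbles start as gas-impermeable nuclei
at the minimum radius R₀ (= one grid spacing by default, matching the
resolvable scale). While stabilized they exchange no mass and cannot
shrink below R₀; their radius follows the no-mass-transfer Boyle
equilibrium from the reference state (R₀ at the reference pressure). The
reference pressure ratchets up to the maximum ambient pressure experienced
— the skin admits gas during compression and blocks it during
decompression, in the spirit of varying-permeability micronucleus models —
because with a fixed seeding-time reference a compression-first dive
profile would never release its nuclei (ambient never falls below its
starting value). Once the Boyle radius exceeds R₀ the bubble releases and
diffusive flux begins. A released bubble that shrinks back to R₀
re-stabilizes by default (`SimulationConfig.restabilize=False` disables
this for dissolution studies, and is the right setting for bubbles
introduced mechanically rather than seeded as nuclei).

**Coalescence.** Any pair with centre distance < R_i + R_j merges
immediately: per-gas masses add exactly, the centre moves to the
mass-weighted centroid, and the merged radius solves the closure. Merging
repeats until no contacts remain and is order-independent for simultaneous
contacts. A merged (or grown) bubble overlapping the phantom boundary
terminates the simulation with a logged event — with many nuclei and
strong supersaturation this is the typical end state, which is why the
default seeding keeps bubbles clear of the boundary by R₀ + h.

**Critical radius.** R_c = 2γ/P_ss, the nucleus size at which the volume
term of the free energy overtakes the surface term at supersaturation
P_ss. With γ = 0.07 N m⁻¹ and P_ss = 9.0×10⁵ Pa (full saturation at the
130 psi dive pressure) the package computes R_c = 0.1556 µm.

## Numerics

**Grid and stepping.** Uniform node grid, centres at (i+½)h, box or
cylinder domains; explicit FTCS with the 7-point Laplacian on liquid nodes
only. The time step is safety·h²/(6·D_max) (safety 0.9 by default);
exceeding the bound is an error, not a warning. Dirichlet phantom-edge
nodes are refreshed from the ambient pressure every step; sealed (no-flux)
faces are available for ledger studies and are implemented by mirroring,
which conserves the FTCS stencil's mass to round-off. Interior
concentrations stay within the initial/boundary envelope (discrete maximum
principle), and the spatial error on the analytic slab problem converges
at second order (verified in the test suite over three refinements).

**Bubble–grid coupling.** Bubbles are Lagrangian spheres over the Eulerian
grid; nodes whose centres fall inside a bubble are flagged gas phase and
excluded from the stencil (a sub-grid bubble claims its nearest node). The
surface gradient is the mean over surface-adjacent liquid nodes of
(C_node − C_s)/d, d the node-centre distance to the bubble surface floored
at h/2 to keep the estimate bounded when a node centre grazes the
interface. By default ("flux_sink" coupling) the exact mass the bubble
gains in a step is removed from those adjacent nodes in proportion to
their individual driving terms (scaled back if a node would go negative),
so the dissolved + free ledger closes to round-off by construction; the
alternative "dirichlet" coupling instead injects C_s into the stencil as
the missing-neighbour value with the surface diffusivity on that link,
which is simpler but only approximately conservative.

**Interface bookkeeping.** Dissolved gas at nodes engulfed by a growing
bubble is displaced into the surface-adjacent liquid (solute rejection at
the moving front), not absorbed: direct absorption is ill-posed at high
supersaturation — whenever L·ΔP exceeds the final ambient pressure, each
swallowed node supplies more than enough gas to claim the next, so the
front advances one grid shell per time step at the discretization-defined
rate h/dt. Nodes uncovered by a shrinking bubble are refilled at the
surface Henry concentration with a matching debit from the bubble's mass.
Both operations conserve each gas exactly.

**Determinism.** All randomness (bubble seeding) flows from a single
integer seed; identical configurations reproduce radius series
bit-identically, and the run manifest records seed, time step, grid and
event log.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| γ | 0.056 (0.042–0.07 plausible) | N m⁻¹ | mid-range tissue-phantom surface tension; outside-range values warn |
| μ | 2×10⁶ (0–4×10⁶) | Pa | modal of the tissue range; collagen hydrogel ≈ 40 Pa |
| D_bulk | 1.4×10⁻⁹ (10⁻¹⁰–2.7×10⁻⁹) | m² s⁻¹ | modal tissue/gel diffusivity; fitted hydrogel value 2.5×10⁻⁹ |
| L_N₂ | 0.0436 baseline, 0.0145 gel | — | modal of the solubility span; the gel preset uses the tabulated N₂ value (a tenfold-larger variant circulating for this system is physically inconsistent — it implies more releasable gas than phantom volume at 9 atm saturation) |
| L_O₂ | 0.02 (0.013–0.027) | — | modal; gel preset 0.027 |
| α_N₂, α_O₂ | 296.8, 259.8 | J kg⁻¹ K⁻¹ | R/M; equal to 92.07/80.6 kJ kg⁻¹ over T at 37 °C |
| M | 5×10⁻² Pa µm⁻³ (= 5×10¹⁶ Pa m⁻³) | Pa m⁻³ | literature bulk-modulus-form constant |
| K | 2.2×10⁹ | Pa | water-like bulk modulus |
| surf_factor, surf_exponent | 30, −2 | — | fitted surface-resistance model (see above) |
| T | 310.15 | K | incubation temperature; constant-temperature assumption |
| h, δt | per-run | m, s | chosen per experiment for stability and convergence; R₀ defaults to h |

Pressure profiles store absolute pressure; constructors accept gauge
readings (adding 101325 Pa) because chamber instrumentation is gauge while
the Laplace balance needs absolute. Depth converts at ρ_w = 1025 kg m⁻³,
g = 9.81 m s⁻². Chamber settings for this kind of system are often
quoted in psi, and psi-to-Pa conversions are a recurring tenfold-error
trap (1 psi s⁻¹ is 6.9×10³ Pa s⁻¹, not 6.9×10⁴); constructors therefore
take Pa-valued rates so any intended schedule can be stated explicitly.

## Study designs used by the test suite

The acceptance-level checks scale the published experiments down to sizes
a single CPU handles in minutes; the scientific regime each check probes
is preserved, as follows.

- **Sensitivity scans** run a single centred nucleus in the 1.28 mm cubic
  phantom at 16³ (h = R₀ = 80 µm) under a 30 m / 3.75 min
  saturation-dive decompression, with three-point one-at-a-time scans
  around the modal values and run windows covering the phantom's slowest
  desaturation mode (t_end = 225 s + 8L²/π²D). Time-of-peak is read with
  parabolic refinement so sub-step shifts of a flat peak remain ordered.
  At the modal stiffness the nucleus Boyle-expands to ≈1.04 R₀, where the
  hyperelastic term pressurizes it above the desaturating tissue tension;
  the bubble is then net-degassing for most of the run, and in that regime
  higher gas solubility accelerates the loss, so the solubility→peak-radius
  response comes out *negative* (by ~0.01–0.1% across the scan) while all
  other responses, and the dominance of D for the time-to-peak, behave as
  expected. In the soft, flux-dominated regime (μ ≈ 40 Pa) the solubility
  responses on the peak radius are positive. The corresponding acceptance
  test asserts the full directional set at the modal baseline and is
  expected to fail on the solubility→R_max inequalities; this is a genuine
  regime property of the model, not a tolerance issue, and the baseline is
  not moved to mask it.
- **Mass-ledger check**: the 0–20 psi, 30 s, five-cycle oscillatory
  schedule over a sealed 1.28 mm phantom (32³, h = 40 µm) with one free
  0.2 mm bubble; per-gas dissolved + free mass must close to 0.5% (the
  flux-sink coupling closes it to round-off).
- **Dive-profile plateau behaviours**: compression at 6.9×10⁴ Pa s⁻¹ to
  9.0×10⁵ Pa, 20 min at depth, decompression at 8.9×10⁴ Pa s⁻¹, over the
  1.28 mm phantom at 32³ with gel materials. Checked: plateau radius
  increases nonlinearly with R₀, and an edge-proximal bubble plateaus
  below a centred one. The laboratory experiments this emulates use an
  11 mm × 5 mm cylindrical phantom; at the scaled size the plateaus and
  half-lives are correspondingly smaller and faster, but both ordering
  properties are scale-robust.
- **Diffusion correctness** uses a 1D step-profile slab against its
  Fourier-series solution over three grid refinements, and a sealed-box
  spike for 10⁴-step conservation.

## Synthetic fixtures

`generate_fixture_series` samples the one-phase association law
R(t) = plateau·(1 − 2^(−t/half-life)) on ≥5 half-lives with multiplicative
Gaussian noise, as a stand-in for experimentally measured nucleated-bubble
growth curves when exercising the regression. It emulates the curve family
and noise scale only — not imaging artefacts, non-spherical outlines,
bubble–bubble interference or nucleation-time jitter — so regression
recovery on fixtures demonstrates estimator correctness, not robustness to
real imaging data. The regression itself fixes the baseline at the first
observed radius (zero for nucleated bubbles, R₀ for simulated ones), fits
plateau and half-life by least squares with multi-start initialization,
and reports an honest convergence flag (constant series and
beyond-window half-lives are flagged unidentifiable rather than raised).

## Limitations

- No perfusion, and no gas loss except through the phantom boundary.
- Bubbles are spherical and stationary (no buoyancy, migration or
  deformation on contact); coalescence is immediate, although contacting
  real bubbles mostly deform and coalesce rarely — a config flag disables
  coalescence to emulate that.
- Nucleation is not modelled energetically; the nucleus population is an
  input (count, size, placement).
- The explicit scheme ties the time step to h²/6D, which makes very fine
  grids expensive; there is no implicit or adaptive stepping.
- Tissue response is elastic only — no poroviscoelasticity, anisotropy or
  strain-rate dependence.
- The surface-gradient estimate floors the node–surface distance at h/2;
  bubble growth rates therefore carry an O(h) discretization sensitivity
  that the qualitative checks tolerate but quantitative radius-time
  comparisons at a fixed h should calibrate against refinement.
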