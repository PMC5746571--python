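# bubblephantom

Three-dimensional finite-difference simulation of gas-bubble growth and
dissolution in soft tissue phantoms under time-varying ambient pressure.

When tissue loaded with dissolved gas at depth is decompressed, the excess
gas can come out of solution as bubbles — the physical origin of
decompression sickness (DCS). Dive-computer algorithms rest on mechanistic
models of this process that are hard to validate *in vivo*. This package
implements an *in silico* counterpart of a collagen-gel tissue phantom: a
bounded diffusion domain with Henry's-law edges, seeded with stabilized
micronuclei, driven by an arbitrary ambient-pressure schedule. It is aimed
at researchers studying extravascular bubble dynamics and at anyone
developing or stress-testing dive-algorithm components.

## Model

Dissolved transport of each gas g (O₂ and N₂) obeys Fickian diffusion,

    ∂C↑g/∂t = D↑g ∇²C↑g ,

with Henry's-law concentrations C = L·p/(αT) at the phantom edge and at
bubble surfaces (L the Ostwald solubility, α the specific gas constant, T
fixed at 310.15 K). Each bubble is a sphere whose internal pressure
satisfies the Young–Laplace balance with a tissue-response term,

    P_B = P_amb + 2γ/R_B + Ω(R_B) ,

where Ω is selectable: none, bulk-modulus (M·ΔV), linear-elastic
continuity-of-displacement, linear-elastic reference-configuration, or the
default incompressible neo-Hookean (hyperelastic) cavitation law
Ω = (μ/2)(5 − 4(R₀/R_B) − (R₀/R_B)⁴). Bubble mass changes by Fick's first
law across the interface, dm/dt = 4πR_B²·D_surf·∂C/∂r, with a reduced
surface diffusivity D_surf = (D_bulk/30)(R_B/R₀)² that scales with the
bubble's surface area; the radius then solves the Laplace/perfect-gas
closure each step. Micronuclei are held gas-impermeable at their minimum
radius R₀ until decompression expands them past R₀ (Boyle's law), after
which diffusive mass flux is enabled. Contacting bubbles coalesce
immediately into a single bubble with the summed gas mass. A critical
nucleation radius R_c = 2γ/P_ss connects the ambient schedule to the
nucleus sizes that can grow at a given supersaturation P_ss.

The solver is an explicit 7-point FTCS scheme on a uniform node grid (box
or cylinder domains), with the time step capped at the 3-D stability bound
h²/6D. The bubble–field exchange is exactly mass-conserving: the dissolved
plus free gas ledger closes to round-off in sealed domains.

## Worked example

A 1.28 mm collagen-gel phantom containing one stabilized micronucleus
(R₀ = 0.08 mm) is compressed at 6.9×10⁴ Pa s⁻¹ to 9.0×10⁵ Pa (≈130 psi),
held 20 minutes while gas loads through the Henry edges, then decompressed
at 8.9×10⁴ Pa s⁻¹:

```python
import bubblephantom as bp

grid = bp.GridSpec(h=8e-5, shape=(16, 16, 16))          # 1.28 mm cube phantom
mixture = bp.air_mixture(L_N2=0.0145, L_O2=0.027, D=2.5e-9)
material = bp.MaterialParams(gamma=0.07, mu=40.0)        # collagen hydrogel
profile = bp.make_ramp_hold_ramp(
    P_surface=1.01325e5, P_depth=9.0e5,
    compression_rate=6.9e4, hold_time=1200.0, decompression_rate=8.9e4,
)
config = bp.SimulationConfig(
    grid=grid, mixture=mixture, material=material, profile=profile,
    n_bubbles=1, placement=[[6.4e-4] * 3],               # centred nucleus, R_0 = h
    t_end=profile.duration + 400.0,
)
result = bp.run_simulation(config)
series = result.series[0]

R_max, t_max = bp.max_radius_metrics(series)
fit = bp.fit_growth_curve(series.after(profile.duration))
print(f"release events : {[e for e in result.events if e['event'] == 'release']}")
print(f"peak radius    : {R_max * 1e3:.3f} mm at t = {t_max:.0f} s")
print(f"plateau radius : {fit.plateau * 1e3:.3f} mm")
print(f"half-life      : {fit.half_life:.1f} s")
print(f"critical radius: {bp.critical_radius(9.0e5, 0.07) * 1e6:.3f} um")
```

Output:

```
release events : [{'t': 1211.904, 'event': 'release', 'bubble_id': 0}]
peak radius    : 0.187 mm at t = 1309 s
plateau radius : 0.187 mm
half-life      : 9.9 s
critical radius: 0.156 um
```

The nucleus stays clamped at 0.08 mm through compression and the hold
(the no-flux skin blocks dissolution), releases the moment decompression
starts (t ≈ 1212 s), expands by Boyle's law and then grows diffusively on
the phantom's supersaturation to a 0.187 mm plateau. The regression
summarizes the post-decompression growth by its plateau radius and
half-life — the same two metrics used to compare simulated and
experimentally imaged bubbles. The critical radius says that after full
saturation at this depth, any nucleus larger than ≈0.16 µm grows rather
than dissolves, which is why spontaneous nucleation is abundant after long
holds.

A command-line interface wraps the same functionality:

```
bubblephantom simulate --config run.toml --out results/
bubblephantom metrics --in results/radius_timeseries.csv
bubblephantom elasticity-table --mu 40 --out forms.csv
bubblephantom sensitivity --config run.toml --param D --values 1e-10,1.4e-9,2.7e-9
bubblephantom fixtures --plateau 2e-4 --half-life 300 --out fixture.csv
```

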