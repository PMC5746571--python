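"""Bubble updates, stabilized nuclei, coalescence, seeding, simulation loop."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import kstest

from bubblephantom import (
    BubbleState,
    DomainContactError,
    GridSpec,
    MaterialParams,
    PressureProfile,
    SimulationConfig,
    SurfaceDiffusionModel,
    air_mixture,
    detect_and_coalesce,
    run_simulation,
    seed_bubbles,
    stabilized_nucleus_step,
    surface_diffusion_coefficient,
    total_gas_mass,
    update_radius,
)
from bubblephantom.core import ALPHA_N2, ALPHA_O2
from bubblephantom.dynamics import masses_for_radius, radius_from_masses
from bubblephantom.profiles import make_oscillatory


def frictionless_material():
    """No surface tension, no tissue response: pure gas-law bubble."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MaterialParams(gamma=0.0, mu=0.0, elasticity_form="none")


class TestSurfaceDiffusion:
    def test_reference_value_at_initial_radius(self):
        m = SurfaceDiffusionModel(factor=30.0)
        assert surface_diffusion_coefficient(m, 2.5e-9, 1e-4, 1e-4) == pytest.approx(
            2.5e-9 / 30.0
        )

    def test_degenerate_no_resistance_case(self):
        m = SurfaceDiffusionModel(factor=1.0, exponent=0)
        assert surface_diffusion_coefficient(m, 2.5e-9, 5e-4, 1e-4) == 2.5e-9

    @pytest.mark.parametrize(
        "exponent,expected",
        [(2, 1.4e-9 / 120.0), (-2, 4 * 1.4e-9 / 30.0)],
    )
    def test_power_law_hand_values_at_doubled_radius(self, exponent, expected):
        m = SurfaceDiffusionModel(factor=30.0, exponent=exponent)
        assert surface_diffusion_coefficient(m, 1.4e-9, 2e-4, 1e-4) == pytest.approx(expected)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            SurfaceDiffusionModel(factor=0.5)


class TestRadiusClosure:
    def test_round_trip_masses_to_radius(self, gel_material):
        mix = air_mixture()
        mass = masses_for_radius(1.7e-4, 1.2e5, gel_material, mix, 1e-4)
        R = radius_from_masses(mass, 1.2e5, gel_material, mix, 1e-4, R_guess=1e-4)
        assert R == pytest.approx(1.7e-4, rel=1e-12)

    def test_ideal_gas_closed_form(self):
        mat = frictionless_material()
        mix = air_mixture()
        m_N2 = 1e-12
        mass = np.array([m_N2, 0.0])
        # P V = m alpha T with V = 4/3 pi R^3
        R_expected = (3 * m_N2 * ALPHA_N2 * mix.temperature / (4 * math.pi * 1e5)) ** (1 / 3)
        # O2 mass zero is allowed
        R = radius_from_masses(mass, 1e5, mat, mix, 1e-5)
        assert R == pytest.approx(R_expected, rel=1e-12)


class TestUpdateRadius:
    def test_equilibrium_fixed_point(self, gel_material):
        mix = air_mixture()
        mass = masses_for_radius(2e-4, 1.5e5, gel_material, mix, 1e-4)
        b = BubbleState(center=np.zeros(3), R_B=2e-4, R_0=1e-4, mass=mass, stabilized=False)
        update_radius(b, np.zeros(2), 1.5e5, gel_material, mix, dt=0.1)
        assert b.R_B == pytest.approx(2e-4, rel=1e-12)

    def test_positive_gradients_grow_the_bubble(self, gel_material):
        mix = air_mixture()
        mass = masses_for_radius(2e-4, 1.5e5, gel_material, mix, 1e-4)
        b = BubbleState(center=np.zeros(3), R_B=2e-4, R_0=1e-4, mass=mass, stabilized=False)
        update_radius(b, np.array([1e3, 1e3]), 1.5e5, gel_material, mix, dt=0.1)
        assert b.R_B > 2e-4

    def test_stabilized_bubble_rejected(self, gel_material):
        mix = air_mixture()
        b = BubbleState(center=np.zeros(3), R_B=1e-4, R_0=1e-4,
                        mass=np.array([1e-12, 1e-13]), stabilized=True)
        with pytest.raises(ValueError):
            update_radius(b, np.zeros(2), 1e5, gel_material, mix, dt=0.1)

    def test_matches_high_resolution_ode_oracle(self):
        """Fixed supersaturated far field, gamma = 0, no tissue response:
        the stepped radius trajectory must track an independent fine-step
        ODE integration of the mass-flux law to 0.1%."""
        mat = frictionless_material()
        mix = air_mixture()
        T = mix.temperature
        alphas = np.array([ALPHA_N2, ALPHA_O2])
        Ls = np.array([s.L for s in mix.species])
        Ds = np.array([s.D_bulk for s in mix.species])
        P_amb, R_0, delta = 1.0e5, 1e-4, 2e-5
        model = SurfaceDiffusionModel(factor=30.0, exponent=-2)
        # 60% supersaturated far field
        C_far = 1.6 * Ls * mix.fractions * P_amb / (alphas * T)
        m0 = masses_for_radius(R_0, P_amb, mat, mix, R_0)

        def radius_of(m):
            return (3 * np.dot(m, alphas) * T / (4 * math.pi * P_amb)) ** (1 / 3)

        def rhs(t, m):
            R = radius_of(m)
            V = 4 / 3 * math.pi * R**3
            C_s = Ls * m / V
            D_surf = (Ds / model.factor) * (R_0 / R) ** model.exponent
            return 4 * math.pi * R**2 * D_surf * (C_far - C_s) / delta

        t_end = 400.0
        sol = solve_ivp(rhs, (0, t_end), m0, rtol=1e-10, atol=1e-22, dense_output=True)

        b = BubbleState(center=np.zeros(3), R_B=R_0, R_0=R_0, mass=m0.copy(),
                        stabilized=False)
        n_steps = 8000
        dt = t_end / n_steps
        checks = 0
        for i in range(n_steps):
            V = b.volume
            C_s = Ls * b.mass / V
            grads = (C_far - C_s) / delta
            update_radius(b, grads, P_amb, mat, mix, dt)
            if (i + 1) % 1000 == 0:
                R_oracle = radius_of(sol.sol((i + 1) * dt))
                assert b.R_B == pytest.approx(R_oracle, rel=1e-3)
                checks += 1
        assert checks == 8
        assert b.R_B > 1.1 * R_0  # the far field actually drove growth


class TestStabilizedNucleus:
    def setup_method(self):
        self.mix = air_mixture()
        self.mat = MaterialParams(gamma=0.056, mu=2e6)

    def _nucleus(self, P0=4.0e5):
        mass = masses_for_radius(1e-4, P0, self.mat, self.mix, 1e-4)
        return BubbleState(center=np.zeros(3), R_B=1e-4, R_0=1e-4, mass=mass,
                           stabilized=True, P_ref=P0)

    def test_unchanged_pressure_keeps_the_nucleus(self):
        b = self._nucleus()
        stabilized_nucleus_step(b, 4.0e5, 4.0e5, self.mat, self.mix)
        assert b.stabilized and b.R_B == 1e-4

    def test_compression_clamps_at_minimum_size_and_ratchets_reference(self):
        b = self._nucleus()
        stabilized_nucleus_step(b, 9.0e5, 4.0e5, self.mat, self.mix)
        assert b.stabilized
        assert b.R_B == 1e-4
        assert b.P_ref == 9.0e5

    def test_decompression_releases_the_nucleus(self):
        b = self._nucleus()
        stabilized_nucleus_step(b, 1.0e5, 4.0e5, self.mat, self.mix)
        assert not b.stabilized
        assert b.R_B > 1e-4


class TestCoalescence:
    def _free_bubble(self, center, R, bid, mat, mix):
        mass = masses_for_radius(R, 1e5, mat, mix, R)
        return BubbleState(center=np.asarray(center, dtype=float), R_B=R, R_0=R,
                           mass=mass, stabilized=False, bubble_id=bid)

    def test_equal_pair_volume_additivity(self):
        mat = frictionless_material()
        mix = air_mixture()
        R = 1e-4
        pair = [
            self._free_bubble([0, 0, 0], R, 0, mat, mix),
            self._free_bubble([1.5 * R, 0, 0], R, 1, mat, mix),
        ]
        merged = detect_and_coalesce(pair, 1e5, mat, mix)
        assert len(merged) == 1
        assert merged[0].R_B == pytest.approx(2 ** (1 / 3) * R, rel=1e-12)

    def test_no_contact_returns_list_unchanged(self, gel_material):
        mix = air_mixture()
        pair = [
            self._free_bubble([0, 0, 0], 1e-4, 0, gel_material, mix),
            self._free_bubble([5e-4, 0, 0], 1e-4, 1, gel_material, mix),
        ]
        out = detect_and_coalesce(pair, 1e5, gel_material, mix)
        assert [b.bubble_id for b in out] == [0, 1]
        assert out[0].R_B == 1e-4

    def test_triple_merge_is_order_independent_and_mass_conserving(self, gel_material):
        mix = air_mixture()
        R = 1e-4
        centers = [[0, 0, 0], [1.6 * R, 0, 0], [0.8 * R, 1.4 * R, 0]]
        radii_seen, masses_seen = [], []
        for perm in itertools.permutations(range(3)):
            bubbles = [
                self._free_bubble(centers[i], R * (1 + 0.1 * i), i, gel_material, mix)
                for i in perm
            ]
            total_in = sum(b.mass.sum() for b in bubbles)
            merged = detect_and_coalesce(bubbles, 1e5, gel_material, mix)
            assert len(merged) == 1
            assert merged[0].mass.sum() == pytest.approx(total_in, rel=1e-12)
            radii_seen.append(merged[0].R_B)
            masses_seen.append(merged[0].mass.copy())
        assert np.ptp(radii_seen) <= 1e-12 * radii_seen[0]
        for m in masses_seen[1:]:
            np.testing.assert_allclose(m, masses_seen[0], rtol=1e-12)

    def test_merged_bubble_overlapping_boundary_terminates(self, gel_material):
        mix = air_mixture()
        grid = GridSpec(h=2e-5, shape=(8, 8, 8))  # 0.16 mm box
        R = 7.2e-5
        pair = [
            self._free_bubble([7e-5, 8e-5, 8e-5], R, 0, gel_material, mix),
            self._free_bubble([9e-5, 8e-5, 8e-5], R, 1, gel_material, mix),
        ]
        with pytest.raises(DomainContactError):
            detect_and_coalesce(pair, 1e5, gel_material, mix, grid=grid)


class TestSeeding:
    def _config(self, n, seed=0):
        grid = GridSpec(h=4e-5, shape=(32, 32, 32))
        return SimulationConfig(
            grid=grid,
            mixture=air_mixture(),
            material=MaterialParams(gamma=0.056, mu=2e6),
            profile=PressureProfile(np.array([0.0, 10.0]), np.array([4e5, 1e5])),
            n_bubbles=n,
            seed=seed,
        )

    def test_zero_bubbles_gives_empty_list(self, rng):
        assert seed_bubbles(self._config(0), rng) == []

    def test_same_seed_reproduces_placements(self):
        cfg = self._config(5)
        a = seed_bubbles(cfg, np.random.default_rng(42))
        b = seed_bubbles(cfg, np.random.default_rng(42))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.center, y.center)

    def test_bubbles_keep_clear_of_boundary_and_each_other(self):
        cfg = self._config(8)
        bubbles = seed_bubbles(cfg, np.random.default_rng(3))
        margin = cfg.R_0 + cfg.grid.h
        ext = cfg.grid.extent
        for b in bubbles:
            assert np.all(b.center >= margin) and np.all(b.center <= np.array(ext) - margin)
            assert b.stabilized and b.R_B == cfg.R_0
        for i in range(len(bubbles)):
            for j in range(i + 1, len(bubbles)):
                d = np.linalg.norm(bubbles[i].center - bubbles[j].center)
                assert d > 2 * cfg.R_0

    def test_positions_are_uniform_per_axis(self):
        # 10^4 single-bubble seedings; KS test against uniform at the 1% level
        cfg = self._config(1)
        rng = np.random.default_rng(2024)
        pts = np.array([seed_bubbles(cfg, rng)[0].center for _ in range(10_000)])
        margin = cfg.R_0 + cfg.grid.h
        lo, hi = margin, cfg.grid.extent[0] - margin
        for axis in range(3):
            u = (pts[:, axis] - lo) / (hi - lo)
            assert kstest(u, "uniform").pvalue > 0.01


class TestRunSimulation:
    def test_constant_pressure_keeps_nuclei_stabilized(self, gel_material, gel_mixture):
        grid = GridSpec(h=8e-5, shape=(8, 8, 8))
        profile = PressureProfile(np.array([0.0, 60.0]), np.array([1.0e5, 1.0e5]))
        cfg = SimulationConfig(grid=grid, mixture=gel_mixture, material=gel_material,
                               profile=profile, n_bubbles=2, seed=5)
        res = run_simulation(cfg)
        for s in res.series:
            assert np.all(s.R == cfg.R_0)
        assert all(b.stabilized for b in res.state.bubbles)
        assert not res.terminated

    def test_identical_configs_are_bit_identical(self, gel_material, gel_mixture):
        grid = GridSpec(h=8e-5, shape=(8, 8, 8))
        profile = PressureProfile(np.array([0.0, 40.0]), np.array([3e5, 1.0e5]))

        def once():
            cfg = SimulationConfig(grid=grid, mixture=gel_mixture, material=gel_material,
                                   profile=profile, n_bubbles=1, seed=11, t_end=80.0)
            return run_simulation(cfg)

        a, b = once(), once()
        np.testing.assert_array_equal(a.series[0].R, b.series[0].R)
        np.testing.assert_array_equal(a.series[0].t, b.series[0].t)

    def test_release_event_logged_on_decompression(self, gel_material, gel_mixture):
        grid = GridSpec(h=8e-5, shape=(8, 8, 8))
        profile = PressureProfile(np.array([0.0, 40.0]), np.array([3e5, 1.0e5]))
        cfg = SimulationConfig(grid=grid, mixture=gel_mixture, material=gel_material,
                               profile=profile, n_bubbles=1, seed=11)
        res = run_simulation(cfg)
        assert any(e["event"] == "release" for e in res.events)
        assert res.series[0].R[-1] > cfg.R_0

    def test_oscillatory_gas_ledger_closes(self, gel_material, gel_mixture):
        grid = GridSpec(h=8e-5, shape=(16, 16, 16), boundary="noflux")
        profile = make_oscillatory(0.0, 1.38e5, 30.0, 2, gauge=True)
        cfg = SimulationConfig(grid=grid, mixture=gel_mixture, material=gel_material,
                               profile=profile, n_bubbles=1, R_0=2e-4,
                               placement=[[8 * 8e-5] * 3],
                               initial_stabilized=False, restabilize=False)
        res = run_simulation(cfg)
        ledger_end = total_gas_mass(res.state, grid, gel_mixture)
        # reconstruct the initial ledger independently
        from bubblephantom import equilibrium_concentration

        P0 = profile.initial_pressure
        n_nodes = np.prod(grid.shape)
        start = np.array([
            equilibrium_concentration(s, s.m_f * P0, gel_mixture.temperature)
            * n_nodes * grid.h**3
            for s in gel_mixture.species
        ]) + masses_for_radius(2e-4, P0, gel_material, gel_mixture, 2e-4)
        np.testing.assert_allclose(ledger_end, start, rtol=5e-3)
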