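import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protocell.physics import (
    N_AVOGADRO,
    EventRule,
    MembraneState,
    PermeabilityCurve,
    ProtocellState,
    check_event,
    divide,
    effective_permeability,
    isotonic_volume,
    lipid_exchange_propensities,
    reduced_surface,
    surface_area,
    surface_fraction_L,
    transport_fluxes,
)
from protocell.networks import SpeciesSpec


class TestSurfaceArea:
    def test_200nm_sphere_census(self):
        # 5,026,548 lipids of 0.2 nm^2 over two leaflets tile a 200 nm sphere
        m = MembraneState(n_l=5_026_548, n_L=0)
        expected = 4.0 * math.pi * (200e-9) ** 2
        assert surface_area(m) == pytest.approx(expected, rel=1e-6)

    def test_empty_membrane_invalid(self):
        with pytest.raises(ValueError):
            MembraneState(n_l=0, n_L=0)

    def test_linearity(self):
        m1 = MembraneState(n_l=10_000, n_L=5_000)
        m2 = MembraneState(n_l=20_000, n_L=10_000)
        assert surface_area(m2) == pytest.approx(2 * surface_area(m1), rel=1e-12)


class TestSurfaceFraction:
    def test_pure_l(self):
        assert surface_fraction_L(MembraneState(n_l=10_000, n_L=0)) == 0.0

    def test_equal_counts_la_dlpc(self):
        m = MembraneState(n_l=5000, n_L=5000, alpha_l=0.2, alpha_L=0.6)
        assert surface_fraction_L(m) == pytest.approx(0.75)

    def test_gml_three_to_one(self):
        m = MembraneState(n_l=7500, n_L=2500, alpha_l=0.2, alpha_L=0.4)
        assert surface_fraction_L(m) == pytest.approx(0.4)


class TestIsotonicVolume:
    def test_numeric_example(self):
        v = isotonic_volume(2.0e6, 100.0)
        assert v == pytest.approx(2.0e6 / (N_AVOGADRO * 100.0), rel=1e-15)
        assert v == pytest.approx(3.321e-20, rel=1e-3)

    def test_linearity(self):
        assert isotonic_volume(4.0e6, 100.0) == pytest.approx(
            2 * isotonic_volume(2.0e6, 100.0), rel=1e-15
        )

    def test_concentration_matches_exactly(self):
        total = 123456.0
        v = isotonic_volume(total, 73.0)
        assert total / (v * N_AVOGADRO) == pytest.approx(73.0, rel=1e-14)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            isotonic_volume(0.0, 100.0)
        with pytest.raises(ValueError):
            isotonic_volume({"A": 1.0}, 0.0)

    def test_mapping_input(self):
        assert isotonic_volume({"A": 1e6, "B": 1e6}, 100.0) == isotonic_volume(2e6, 100.0)


class TestReducedSurface:
    def test_sphere_is_one(self):
        r = 137e-9
        assert reduced_surface(4 * math.pi * r**2, 4 / 3 * math.pi * r**3) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_two_half_spheres(self):
        r = 100e-9
        v = 4 / 3 * math.pi * r**3
        r_half = (3 * (v / 2) / (4 * math.pi)) ** (1 / 3)
        s = 2 * 4 * math.pi * r_half**2
        assert reduced_surface(s, v) == pytest.approx(2 ** (1 / 3), abs=1e-12)

    def test_monotone_decreasing_in_volume(self):
        s = 5e-13
        phis = [reduced_surface(s, v) for v in (1e-20, 2e-20, 4e-20)]
        assert phis[0] > phis[1] > phis[2]


class TestPermeabilityCurve:
    def test_nodes_exact(self):
        curve = PermeabilityCurve([(0, 1), (0.5, 10), (1, 2)])
        for x, f in curve.control_points:
            assert curve(x) == f

    def test_lagrange_quadratic_value(self):
        curve = PermeabilityCurve([(0, 1), (0.5, 10), (1, 2)])
        assert curve(0.25) == pytest.approx(7.625, abs=1e-12)

    def test_extrapolation_refused(self):
        curve = PermeabilityCurve([(0, 1), (0.5, 10), (1, 2)])
        with pytest.raises(ValueError):
            curve(1.01)
        with pytest.raises(ValueError):
            curve(-0.01)

    def test_collinear_points_are_linear(self):
        curve = PermeabilityCurve([(0, 1), (0.5, 2), (1, 3)])
        coeffs = curve.coefficients()
        assert abs(coeffs[0]) < 1e-12  # quadratic term vanishes

    def test_needs_endpoints(self):
        with pytest.raises(ValueError):
            PermeabilityCurve([(0.1, 1), (0.5, 10), (1, 2)])

    def test_duplicate_chi_rejected(self):
        with pytest.raises(ValueError):
            PermeabilityCurve([(0, 1), (0, 2), (1, 2)])


class TestEffectivePermeability:
    def test_impermeable_always_zero(self):
        sp = SpeciesSpec("acd", "waste")
        curve = PermeabilityCurve([(0, 1), (0.5, 10), (1, 2)])
        for chi in (0.0, 0.3, 1.0):
            assert effective_permeability(sp, chi, curve) == 0.0

    def test_node_multiplier(self):
        sp = SpeciesSpec(
            "A", "nutrient", "composition_dependent", base_permeability=1e-12,
            env_concentration=1.0,
        )
        curve = PermeabilityCurve([(0, 1), (0.5, 10), (1, 2)])
        assert effective_permeability(sp, 0.5, curve) == pytest.approx(1e-11)

    def test_constant_ignores_curve(self):
        sp = SpeciesSpec(
            "w", "waste", "constant", base_permeability=3e-12, env_concentration=0.0
        )
        curve = PermeabilityCurve([(0, 1), (0.5, 10), (1, 2)])
        assert effective_permeability(sp, 0.5, curve) == 3e-12


class TestTransportFluxes:
    def _species(self):
        return [
            SpeciesSpec("A", "nutrient", "constant", base_permeability=1e-12,
                        env_concentration=100.0),
            SpeciesSpec("acd", "waste"),
        ]

    def test_influx_magnitude(self):
        fluxes = transport_fluxes(
            self._species(), {"A": 0.0, "acd": 50.0}, volume=1e-20, surface=5e-13,
            chi=0.0, curve=None,
        )
        influx, efflux = fluxes["A"]
        assert influx == pytest.approx(1e-12 * 5e-13 * 100.0 * N_AVOGADRO, rel=1e-12)
        assert influx == pytest.approx(30.1, rel=2e-3)
        assert efflux == 0.0

    def test_equilibrium_symmetry(self):
        v = 1e-20
        n_eq = 100.0 * v * N_AVOGADRO
        fluxes = transport_fluxes(
            self._species(), {"A": n_eq, "acd": 0.0}, volume=v, surface=5e-13,
            chi=0.0, curve=None,
        )
        influx, efflux = fluxes["A"]
        assert influx == pytest.approx(efflux, rel=1e-12)

    def test_impermeable_zero(self):
        fluxes = transport_fluxes(
            self._species(), {"A": 0.0, "acd": 1e6}, volume=1e-20, surface=5e-13,
            chi=0.0, curve=None,
        )
        assert fluxes["acd"] == (0.0, 0.0)


class TestLipidExchange:
    def test_channel_structure(self):
        state = ProtocellState(0.0, {}, MembraneState(n_l=10_000, n_L=2_000))
        props = lipid_exchange_propensities(
            state, volume=1e-20, surface=5e-13, c_l_env=0.5,
            k_in=1e-13, k_out=1e-5, k_ins=1e-11, k_d=0.1, aqueous_L=500.0,
        )
        assert set(props) == {"l_uptake", "l_release", "L_insert", "displacement"}
        assert props["l_release"] == pytest.approx(1e-5 * 10_000)
        assert props["displacement"] == pytest.approx(0.1 * 2_000)
        assert all(v >= 0 for v in props.values())

    def test_displacement_conserves_census(self):
        # one L out, one l in: total count before == after, by construction
        n_l, n_L = 10_000, 2_000
        assert (n_l + 1) + (n_L - 1) == n_l + n_L


class TestEvents:
    def test_divide_threshold(self):
        assert check_event(1.30, EventRule()) == "divide"

    def test_burst_threshold(self):
        assert check_event(0.85, EventRule()) == "burst"

    def test_sphere_is_quiet(self):
        assert check_event(1.00, EventRule()) == "none"

    def test_rule_sanity(self):
        with pytest.raises(ValueError):
            EventRule(phi_divide=0.9)


class TestDivide:
    def _mother(self, counts=None):
        return ProtocellState(
            t=10.0,
            counts=counts or {"AB": 10},
            membrane=MembraneState(n_l=10_000, n_L=4_000),
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_conserved_every_seed(self, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = divide(self._mother(), rng)
        assert d1.counts["AB"] + d2.counts["AB"] == 10
        assert d1.membrane.n_l + d2.membrane.n_l == 10_000
        assert d1.membrane.n_L + d2.membrane.n_L == 4_000

    def test_binomial_mean(self):
        rng = np.random.default_rng(0)
        total = 0
        n = 400
        for _ in range(n):
            d1, _ = divide(self._mother({"AB": 10}), rng)
            total += d1.counts["AB"]
        assert total / n == pytest.approx(5.0, abs=0.3)

    def test_equal_split_phi_ratio(self):
        # daughters of a mother at the division threshold are spheres
        mother_s = 5e-13
        mother_v = (mother_s / 2 ** (1 / 3)) ** 1.5 / (6 * math.sqrt(math.pi))
        assert reduced_surface(mother_s, mother_v) == pytest.approx(2 ** (1 / 3), rel=1e-9)
        d_phi = reduced_surface(mother_s / 2, mother_v / 2)
        assert d_phi == pytest.approx(1.0, abs=1e-9)

    def test_generation_bookkeeping(self):
        rng = np.random.default_rng(1)
        d1, d2 = divide(self._mother(), rng)
        assert d1.generation == d2.generation == 1
        assert d1.lineage_id != d2.lineage_id

    @given(n=st.integers(0, 10_000), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, n, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = divide(self._mother({"Z": n}), rng)
        assert d1.counts["Z"] + d2.counts["Z"] == n
        assert d1.counts["Z"] >= 0 and d2.counts["Z"] >= 0
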