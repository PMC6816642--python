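"""Scaling law, percolation correction, inversion and uncertainty propagation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanometering import (
    DiffusivityConstants,
    Interface,
    MeteringSystem,
    concentration,
    confined_volume,
    cpt_forward,
    cpt_inverse,
    estimate_particle_count,
    invert_theta_star,
    propagate_uncertainty,
    propagate_uncertainty_mc,
    scaled_diffusivity,
)

CONST = DiffusivityConstants()


def row2_system(**overrides):
    """Iron-oxide nanoparticle benchmark system (8 particles, 8.13 nm pore)."""
    kwargs = dict(
        pore_wall=Interface(sas=140.47, delta=0.33),
        particle=Interface(sas=21.64, delta=0.50),
        V_tot=180.90,
    )
    kwargs.update(overrides)
    return MeteringSystem(**kwargs)


class TestScalingLaw:
    @pytest.mark.parametrize(
        "theta_star, expected",
        [
            (0.0, 2.60e-9),  # bulk limit
            (1.0, 0.39e-9),  # fully confined limit
            (0.57, 1.3403e-9),  # benchmark row prints D = 1.33e-9
        ],
    )
    def test_forward_values(self, theta_star, expected):
        assert scaled_diffusivity(theta_star) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize(
        "D, expected",
        [
            (2.60e-9, 0.0),
            (1.33e-9, 0.574661),
            (6.63e-10, 0.876471),
        ],
    )
    def test_inverse_values(self, D, expected):
        assert invert_theta_star(D) == pytest.approx(expected, abs=1e-6)

    def test_linear_strictly_decreasing(self):
        ts = np.linspace(0, 1, 101)
        d = np.array([scaled_diffusivity(t) for t in ts])
        assert np.all(np.diff(d) < 0)
        assert np.allclose(np.diff(d, 2), 0.0, atol=1e-24)

    @pytest.mark.parametrize("bad", [-0.1, 1.0001])
    def test_forward_domain(self, bad):
        with pytest.raises(ValueError):
            scaled_diffusivity(bad)

    def test_inverse_domain(self):
        with pytest.raises(ValueError, match="faster than bulk"):
            invert_theta_star(2.7e-9)
        with pytest.raises(ValueError, match="full-confinement floor"):
            invert_theta_star(0.39e-9)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    def test_round_trip(self, x):
        assert invert_theta_star(scaled_diffusivity(x)) == pytest.approx(
            x, abs=1e-12
        )


class TestPercolationCorrection:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.0, 0.0), (0.85, 0.5726), (2.09, 0.8763)],
    )
    def test_forward(self, theta, expected):
        assert cpt_forward(theta) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "theta_star, expected",
        [(0.0, 0.0), (0.57, 0.8440), (0.876471, 2.0913)],
    )
    def test_inverse(self, theta_star, expected):
        assert cpt_inverse(theta_star) == pytest.approx(expected, abs=1e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            cpt_forward(-0.01)
        with pytest.raises(ValueError):
            cpt_inverse(1.0)

    @given(st.floats(min_value=0.0, max_value=10.0))
    def test_round_trip(self, theta):
        back = cpt_inverse(cpt_forward(theta))
        assert np.isclose(back, theta, rtol=1e-12, atol=1e-12)

    # above theta ~ 36, 1 - exp(-theta) rounds to exactly 1.0 in double
    # precision; the strict bound holds on the representable range
    @given(st.floats(min_value=1e-12, max_value=30.0))
    def test_star_below_apparent_and_below_one(self, theta):
        star = cpt_forward(theta)
        assert star < 1.0
        assert star <= theta  # equality only at float resolution near 0


class TestConfinedVolume:
    def test_single(self):
        assert confined_volume([Interface(sas=10, delta=0.5)]) == pytest.approx(5.0)

    def test_pore_plus_particles(self):
        ifaces = [
            Interface(sas=140.47, delta=0.33, count=1),
            Interface(sas=21.64, delta=0.50, count=8),
        ]
        assert confined_volume(ifaces) == pytest.approx(132.915, abs=1e-3)
        # additive and order-independent
        assert confined_volume(ifaces[::-1]) == confined_volume(ifaces)

    def test_wall_only(self):
        assert confined_volume([Interface(sas=194.00, delta=0.33)]) == pytest.approx(
            64.02, abs=1e-6
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confined_volume([])


class TestParticleCountInversion:
    def test_benchmark_row_ionp8(self):
        res = estimate_particle_count(1.33e-9, row2_system())
        assert res.n_p == pytest.approx(10.06, rel=0.02)
        assert res.theta_star == pytest.approx(0.57, abs=0.01)
        assert res.theta == pytest.approx(0.85, abs=0.01)
        assert not res.clamped

    def test_benchmark_row_ubiquitin(self):
        system = MeteringSystem(
            pore_wall=Interface(sas=194.00, delta=0.33),
            particle=Interface(sas=48.19, delta=0.31),
            V_tot=316.87,
        )
        res = estimate_particle_count(1.55e-9, system)
        assert res.n_p == pytest.approx(9.38, rel=0.02)

    def test_bulk_water_implies_empty_pore(self):
        res = estimate_particle_count(CONST.D_B, row2_system())
        assert res.n_p == 0.0
        assert res.clamped

    def test_monotone_decreasing_in_D(self):
        system = row2_system()
        ds = np.linspace(0.5e-9, 2.6e-9, 200)
        counts = [estimate_particle_count(d, system).n_p for d in ds]
        kept = [c for c in counts if c > 0]  # clamp flattens the tail
        assert np.all(np.diff(kept) < 0)

    def test_no_cpt_option_dilute_limit(self):
        # for small theta the corrected and uncorrected estimates coincide
        d_dilute = scaled_diffusivity(0.01)
        a = estimate_particle_count(d_dilute, row2_system(), apply_cpt=True)
        b = estimate_particle_count(d_dilute, row2_system(), apply_cpt=False)
        assert a.theta == pytest.approx(b.theta, abs=1e-4)


class TestConcentration:
    def test_zero(self):
        c = concentration(0.0, 11.04, 1000.0)
        assert c.number_per_nm3 == 0.0
        assert c.molar_mol_m3 == 0.0

    def test_number_density(self):
        c = concentration(10.0, 11.04, 1000.0)
        assert c.number_per_nm3 == pytest.approx(1.0447e-4, rel=1e-3)

    def test_molar_conversion(self):
        c = concentration(10.0, 11.04, 1000.0, molar_mass=14300.0)
        assert c.molar_mol_m3 == pytest.approx(0.17350, rel=1e-3)
        assert c.mass_g_m3 == pytest.approx(0.17350 * 14300.0, rel=1e-3)

    def test_bad_geometry(self):
        with pytest.raises(ValueError):
            concentration(1.0, -1.0, 10.0)


class TestUncertainty:
    def test_zero_sd(self):
        res = propagate_uncertainty(1.33e-9, 0.0, 0.0, row2_system())
        assert res.n_p_sd == 0.0

    def test_first_order_linearity(self):
        r1 = propagate_uncertainty(1.33e-9, 0.02e-9, 0.0, row2_system())
        r2 = propagate_uncertainty(1.33e-9, 0.04e-9, 0.0, row2_system())
        assert r2.n_p_sd == pytest.approx(2.0 * r1.n_p_sd, rel=1e-12)

    def test_analytic_matches_monte_carlo(self):
        res = propagate_uncertainty(1.33e-9, 0.05e-9, 5.0, row2_system())
        _, mc_sd = propagate_uncertainty_mc(
            1.33e-9, 0.05e-9, 5.0, row2_system(), n_draws=10_000, seed=123
        )
        assert res.n_p_sd == pytest.approx(mc_sd, rel=0.05)

    def test_domain_crossing_falls_back_to_mc(self):
        # 1 s.d. above D reaches past bulk: linearisation unreliable
        res = propagate_uncertainty(2.55e-9, 0.2e-9, 0.0, row2_system())
        assert res.clamped
        assert res.n_p_sd >= 0.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            propagate_uncertainty(1.33e-9, -1e-10, 0.0, row2_system())


class TestInvariants:
    def test_constants_validation(self):
        with pytest.raises(ValueError):
            DiffusivityConstants(D_B=1e-9, D_C=2e-9)

    def test_interface_validation(self):
        with pytest.raises(ValueError):
            Interface(sas=-1.0, delta=0.5)
        with pytest.raises(ValueError):
            Interface(sas=1.0, delta=0.5, count=-1)

    def test_system_validation(self):
        with pytest.raises(ValueError):
            row2_system(V_tot=-5.0)
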