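"""Imbibition and Fickian filling-time models against closed-form oracles."""

import dataclasses
import math

import numpy as np
import pytest

from nanometering import (
    FillingProblem,
    FluidProperties,
    PoreGeometry,
    capillary_pressure,
    diffusion_filling_time,
    filling_sweep,
    imbibition_time,
    permeability,
    solve_fick_1d,
)
from conftest import slab_center_ratio

TABLET = PoreGeometry(d_P=11.04, T=1e6, phi_0=0.4, tau=1.0)  # 1 mm thick
WATER = FluidProperties()


class TestPermeability:
    def test_reference_tablet(self):
        # r_h = 4.97 nm, r_0 = 5.52 nm, phi = 0.4, tau = 1
        assert permeability(TABLET) == pytest.approx(1.0012e-18, rel=1e-3)

    def test_hagen_poiseuille_bundle_limit(self):
        geom = PoreGeometry(d_P=10.0, T=100.0, phi_0=1.0, tau=1.0, n_layers=0)
        r0_m = 5.0e-9
        assert permeability(geom) == pytest.approx(r0_m**2 / 8.0, rel=1e-12)

    def test_tortuosity_proportionality(self):
        geom2 = dataclasses.replace(TABLET, tau=2.0)
        assert permeability(geom2) == pytest.approx(permeability(TABLET) / 2.0)


class TestCapillaryPressure:
    def test_reference_tablet(self):
        assert capillary_pressure(TABLET, WATER) == pytest.approx(2.897e7, rel=1e-3)

    def test_contact_angle_scaling(self):
        tilted = FluidProperties(contact_angle=1.0)
        assert capillary_pressure(TABLET, tilted) == pytest.approx(
            capillary_pressure(TABLET, WATER) * math.cos(1.0)
        )

    def test_inverse_in_hydraulic_radius(self):
        # halving r_h (via d_P) doubles the pressure
        small = PoreGeometry(d_P=2 * 4.97, T=100.0, n_layers=0)
        large = PoreGeometry(d_P=4 * 4.97, T=100.0, n_layers=0)
        assert capillary_pressure(small, WATER) == pytest.approx(
            2.0 * capillary_pressure(large, WATER)
        )


class TestImbibition:
    def test_one_mm_tablet_under_ten_seconds(self):
        t_i = imbibition_time(TABLET, WATER)
        assert t_i == pytest.approx(6.895, rel=1e-3)
        assert t_i <= 10.0

    def test_quadratic_front_scaling(self):
        t_mm = imbibition_time(TABLET, WATER, h=1e-3)
        t_um = imbibition_time(TABLET, WATER, h=1e-6)
        assert t_um == pytest.approx(t_mm * 1e-6, rel=1e-12)

    def test_zero_travel_rejected(self):
        with pytest.raises(ValueError):
            imbibition_time(TABLET, WATER, h=0.0)


@pytest.fixture(scope="module")
def lysozyme_solution(lysozyme_problem):
    return solve_fick_1d(lysozyme_problem, stop_ratio=2.0, max_fo=2.05)


class TestFickSolver:
    def test_limits(self, lysozyme_solution):
        assert lysozyme_solution.center_ratio[0] == 0.0
        assert lysozyme_solution.center_ratio[-1] > 0.9
        assert np.all(np.diff(lysozyme_solution.center_ratio) >= -1e-12)

    def test_matches_series_oracle(self, lysozyme_problem, lysozyme_solution):
        fos = np.linspace(0.01, 2.0, 60)
        alpha = lysozyme_problem.D_p / lysozyme_problem.geom.tau
        times = fos * (lysozyme_problem.thickness_m / 2.0) ** 2 / alpha
        numeric = lysozyme_solution.center_ratio_at(times)
        assert np.abs(numeric - slab_center_ratio(fos)).max() < 5e-3

    def test_profile_symmetry(self, lysozyme_solution):
        profiles = lysozyme_solution.profiles
        assert np.allclose(profiles, profiles[:, ::-1], atol=1e-10)

    def test_porosity_cancels(self, lysozyme_problem):
        # D_e/phi_0 = D_p/tau: the centre-ratio curve is porosity-independent
        lo = dataclasses.replace(
            lysozyme_problem, geom=dataclasses.replace(lysozyme_problem.geom, phi_0=0.2)
        )
        hi = dataclasses.replace(
            lysozyme_problem, geom=dataclasses.replace(lysozyme_problem.geom, phi_0=0.8)
        )
        assert diffusion_filling_time(lo) == pytest.approx(
            diffusion_filling_time(hi), rel=1e-9
        )

    def test_grid_too_coarse_rejected(self, lysozyme_problem):
        with pytest.raises(ValueError):
            solve_fick_1d(lysozyme_problem, n_nodes=5)


class TestFillingTime:
    def test_lysozyme_one_mm(self, lysozyme_problem):
        # series closed form: t = -ln(0.05*pi/4)/pi^2 * T^2/(D_p/tau)
        t_exact = (
            -math.log(0.05 * math.pi / 4.0)
            / math.pi**2
            * (1e-3) ** 2
            / 11.08e-11
        )
        t_d = diffusion_filling_time(lysozyme_problem)
        assert t_d == pytest.approx(t_exact, rel=2e-3)
        assert t_d == pytest.approx(2960.0, rel=2e-3)

    def test_doxorubicin_500_um(self, doxorubicin_problem):
        assert diffusion_filling_time(doxorubicin_problem) == pytest.approx(
            512.5, rel=2e-3
        )

    def test_quadratic_thickness_scaling(self, doxorubicin_problem):
        double = dataclasses.replace(
            doxorubicin_problem,
            geom=dataclasses.replace(doxorubicin_problem.geom, T=1e6),
        )
        assert diffusion_filling_time(double) == pytest.approx(
            4.0 * diffusion_filling_time(doxorubicin_problem), rel=1e-3
        )

    def test_lower_threshold_fills_sooner(self, doxorubicin_problem):
        early = dataclasses.replace(doxorubicin_problem, fill_fraction=0.2)
        assert diffusion_filling_time(early) < diffusion_filling_time(
            doxorubicin_problem
        )


@pytest.fixture(scope="module")
def sweep(lysozyme_problem):
    return filling_sweep(lysozyme_problem, np.logspace(-4, -3, 5))


class TestSweep:
    def test_monotone_columns(self, sweep):
        assert np.all(np.diff(sweep["t_imbibition_s"]) > 0)
        assert np.all(np.diff(sweep["t_diffusion_s"]) > 0)

    def test_diffusion_two_orders_slower(self, sweep):
        ratio = sweep["t_diffusion_s"] / sweep["t_imbibition_s"]
        assert ((ratio > 100) & (ratio < 1000)).all()
        # 1 mm tablet: ~2960 s vs ~6.9 s
        assert ratio.iloc[-1] == pytest.approx(429.0, rel=0.01)

    def test_quadratic_fit_quality(self, sweep):
        t = sweep["thickness_m"].to_numpy()
        td = sweep["t_diffusion_s"].to_numpy()
        a = (td * t**2).sum() / (t**4).sum()  # LS fit of t_D = a·T²
        resid = td - a * t**2
        r2 = 1.0 - (resid**2).sum() / ((td - td.mean()) ** 2).sum()
        assert r2 > 0.9999
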