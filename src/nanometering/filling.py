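"""Pore-filling time models for nanoporous metering tablets.

Two successive, time-scale-separated processes fill an initially dry tablet
immersed in a particle suspension:

1. **Capillary imbibition** of pure water. Under the sharp-front
   approximation, Darcy flow driven by the Young–Laplace capillary pressure
   recovers the Lucas–Washburn form h(t) = sqrt(2·K·Δp·t/(φᵢ·μ)), giving a
   complete-filling time t_i = h²·φᵢ·μ/(2·K·Δp) for front travel h (the tablet
   thickness). The permeability of a bundle of straight cylindrical pores is
   K = r_h⁴·φ₀/(8·r₀²·τ), with hydraulic radius r_h reduced by adsorbed water
   layers.

2. **Fickian particle diffusion** through the now-hydrated pores,
   φ₀·∂c/∂t = D_e·∂²c/∂x² with effective diffusivity D_e = φ₀·D_p/τ
   (equivalently ∂c/∂t = (D_p/τ)·∂²c/∂x²: the porosity cancels), both tablet
   faces held at the bulk concentration and zero initial concentration inside.
   The filling time t_D is the first time the centre concentration reaches a
   set fraction (default 95%) of the bulk value.

The diffusion equation is solved with an unconditionally stable
Crank–Nicolson scheme (with a Rannacher start-up to damp the initial boundary
discontinuity) on a uniform grid, in the dimensionless variables ξ = x/T,
s = (D_p/τ)·t/T²; t_D is then located by monotone (PCHIP) interpolation and
Brent root-finding on the centre-ratio curve. This module works in SI units;
the nm-based :class:`~nanometering.geometry.PoreGeometry` is converted at the
boundary.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.sparse import identity, diags
from scipy.sparse.linalg import splu

from .geometry import PoreGeometry, hydraulic_radius
from .units import NM_TO_M

__all__ = [
    "FluidProperties",
    "FillingProblem",
    "FickSolution",
    "permeability",
    "capillary_pressure",
    "imbibition_time",
    "solve_fick_1d",
    "diffusion_filling_time",
    "filling_sweep",
    "plot_sweep",
]


@dataclass(frozen=True)
class FluidProperties:
    """Imbibing fluid: surface tension [N/m], viscosity [Pa·s], contact angle
    [rad]. Defaults are bulk water at 300 K on silica (ϑ ≈ 0)."""

    surface_tension: float = 0.072
    viscosity: float = 1.0e-3
    contact_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.surface_tension <= 0 or self.viscosity <= 0:
            raise ValueError("surface tension and viscosity must be > 0")
        if not (0.0 <= self.contact_angle < math.pi / 2):
            raise ValueError(
                f"contact angle must be in [0, π/2), got {self.contact_angle}"
            )


@dataclass(frozen=True)
class FillingProblem:
    """Tablet + fluid + solute parameters for the filling-time models.

    D_p : bulk diffusivity of the suspended particle [m²/s]
    c_b : bulk particle concentration at the tablet faces [mol/m³]
    fill_fraction : centre-concentration threshold defining t_D
    """

    geom: PoreGeometry
    D_p: float
    fluid: FluidProperties = field(default_factory=FluidProperties)
    c_b: float = 3.4
    fill_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.D_p <= 0:
            raise ValueError(f"D_p must be > 0, got {self.D_p}")
        if not (0.0 < self.fill_fraction < 1.0):
            raise ValueError(
                f"fill_fraction must be in (0, 1), got {self.fill_fraction}"
            )
        if self.c_b <= 0:
            raise ValueError(f"c_b must be > 0, got {self.c_b}")

    @property
    def thickness_m(self) -> float:
        return self.geom.T * NM_TO_M

    @property
    def effective_diffusivity(self) -> float:
        """D_e = φ₀·D_p/τ [m²/s]."""
        return self.geom.phi_0 * self.D_p / self.geom.tau


def permeability(geom: PoreGeometry) -> float:
    """Permeability of a bundle of straight cylindrical pores [m²]:
    K = (1/8)·r_h⁴·φ₀/(r₀²·τ)."""
    r_h = hydraulic_radius(geom) * NM_TO_M
    r_0 = geom.r_0 * NM_TO_M
    return 0.125 * r_h**4 * geom.phi_0 / (r_0**2 * geom.tau)


def capillary_pressure(geom: PoreGeometry, fluid: FluidProperties | None = None) -> float:
    """Young–Laplace driving pressure Δp = 2·σ·cos(ϑ)/r_h [Pa]."""
    fluid = fluid or FluidProperties()
    r_h = hydraulic_radius(geom) * NM_TO_M
    return 2.0 * fluid.surface_tension * math.cos(fluid.contact_angle) / r_h


def imbibition_time(
    geom: PoreGeometry, fluid: FluidProperties | None = None, h: float | None = None
) -> float:
    """Lucas–Washburn/Darcy complete-imbibition time t_i [s].

    ``h`` is the front travel distance in metres; by default the full tablet
    thickness. t_i = h²·φᵢ·μ/(2·K·Δp), quadratic in h.
    """
    fluid = fluid or FluidProperties()
    if h is None:
        h = geom.T * NM_TO_M
    if h <= 0:
        raise ValueError(f"front travel distance must be > 0, got {h}")
    K = permeability(geom)
    dp = capillary_pressure(geom, fluid)
    if K <= 0 or dp <= 0:
        raise ValueError("no capillary driving (zero permeability or pressure)")
    return h * h * geom.uptake_porosity * fluid.viscosity / (2.0 * K * dp)


@dataclass
class FickSolution:
    """Dense centre-ratio history of the 1D Fickian filling solve.

    times : output instants [s]
    fo : corresponding half-thickness Fourier numbers (D_p/τ)·t/(T/2)²
    x : node coordinates [m]
    center_ratio : c(T/2, t)/c_b at each output instant
    profiles : c(x, t)/c_b, shape (len(times), len(x))
    """

    times: np.ndarray
    fo: np.ndarray
    x: np.ndarray
    center_ratio: np.ndarray
    profiles: np.ndarray

    def center_ratio_at(self, t: float | np.ndarray) -> np.ndarray:
        """Monotone interpolant of the centre-ratio curve."""
        interp = PchipInterpolator(self.times, self.center_ratio)
        return interp(t)


def solve_fick_1d(
    problem: FillingProblem,
    n_nodes: int = 201,
    dt_fo: float = 5e-4,
    stop_ratio: float | None = None,
    max_fo: float = 8.0,
    store_profiles: bool = True,
) -> FickSolution:
    """Solve the slab filling problem with Crank–Nicolson time stepping.

    The dimensionless problem u_s = u_ξξ on ξ ∈ [0, 1], u(0) = u(1) = 1,
    u(ξ, 0) = 0 is advanced with time step ``dt_fo``/4 (``dt_fo`` is expressed
    in units of the half-thickness Fourier number Fo = (D_p/τ)·t/(T/2)²) until
    the centre ratio reaches ``stop_ratio`` (default: comfortably past the
    problem's fill fraction) or ``max_fo``. Four implicit-Euler half-steps
    (Rannacher smoothing) damp the spurious oscillations the initial corner
    discontinuity would otherwise excite in Crank–Nicolson.
    """
    if n_nodes < 11:
        raise ValueError(f"grid too coarse: n_nodes={n_nodes}")
    if dt_fo <= 0:
        raise ValueError(f"dt_fo must be > 0, got {dt_fo}")
    if stop_ratio is None:
        stop_ratio = max(0.999, min(0.9995, problem.fill_fraction + 0.04))

    alpha = problem.D_p / problem.geom.tau  # m²/s; porosity cancels in c/c_b
    T_m = problem.thickness_m
    ds = dt_fo / 4.0  # step in s = alpha·t/T²
    n_steps_max = int(math.ceil(max_fo / dt_fo))

    x = np.linspace(0.0, 1.0, n_nodes)
    dx = x[1] - x[0]
    n_int = n_nodes - 2
    lap = diags(
        [1.0, -2.0, 1.0], [-1, 0, 1], shape=(n_int, n_int), format="csc"
    ) / dx**2
    eye = identity(n_int, format="csc")

    # boundary source: both Dirichlet neighbours are 1
    bvec = np.zeros(n_int)
    bvec[0] = 1.0 / dx**2
    bvec[-1] = 1.0 / dx**2

    lu_cn = splu((eye - 0.5 * ds * lap).tocsc())
    rhs_cn = eye + 0.5 * ds * lap
    lu_be = splu((eye - 0.5 * ds * lap).tocsc())  # backward Euler, step ds/2

    u = np.zeros(n_int)
    mid = n_int // 2  # n_nodes odd -> interior midpoint is the slab centre
    times = [0.0]
    ratios = [0.0]
    profiles = [np.concatenate(([1.0], u, [1.0]))] if store_profiles else None

    s = 0.0
    # Rannacher start-up: 4 backward-Euler half-steps = 2 full steps
    for _ in range(4):
        u = lu_be.solve(u + 0.5 * ds * bvec)
        s += 0.5 * ds
        times.append(s * T_m**2 / alpha)
        ratios.append(float(u[mid]))
        if store_profiles:
            profiles.append(np.concatenate(([1.0], u, [1.0])))

    for _ in range(n_steps_max):
        u = lu_cn.solve(rhs_cn @ u + ds * bvec)
        s += ds
        times.append(s * T_m**2 / alpha)
        ratios.append(float(u[mid]))
        if store_profiles:
            profiles.append(np.concatenate(([1.0], u, [1.0])))
        if u[mid] >= stop_ratio:
            break
    else:
        if ratios[-1] < problem.fill_fraction:
            raise RuntimeError(
                f"centre ratio only reached {ratios[-1]:.4f} < fill fraction "
                f"{problem.fill_fraction} within max_fo={max_fo}"
            )

    times_arr = np.asarray(times)
    return FickSolution(
        times=times_arr,
        fo=alpha * times_arr / (T_m / 2.0) ** 2,
        x=x * T_m,
        center_ratio=np.asarray(ratios),
        profiles=np.asarray(profiles) if store_profiles else np.empty((0, n_nodes)),
    )


def diffusion_filling_time(problem: FillingProblem, **solver_kwargs) -> float:
    """Fickian filling time t_D [s]: first time the centre concentration
    reaches ``fill_fraction``·c_b.

    The centre-ratio curve rises monotonically from 0 to 1, so the crossing is
    unique; it is bracketed on the stored curve and refined by Brent's method
    on a monotone PCHIP interpolant.
    """
    solver_kwargs.setdefault("store_profiles", False)
    sol = solve_fick_1d(problem, **solver_kwargs)
    target = problem.fill_fraction
    idx = int(np.searchsorted(sol.center_ratio, target))
    if idx == 0:
        return 0.0
    if idx >= len(sol.times):
        raise RuntimeError("fill fraction not reached; increase max_fo")
    interp = PchipInterpolator(sol.times, sol.center_ratio)
    return float(
        brentq(lambda t: interp(t) - target, sol.times[idx - 1], sol.times[idx],
               rtol=1e-8)
    )


def filling_sweep(
    problem: FillingProblem, thicknesses_m: np.ndarray | list[float], **solver_kwargs
) -> pd.DataFrame:
    """Imbibition and diffusion filling times across tablet thicknesses.

    Returns a DataFrame with columns ``thickness_m``, ``t_imbibition_s``,
    ``t_diffusion_s``, ``center_ratio_final``.
    """
    rows = []
    for T_m in np.asarray(thicknesses_m, dtype=float):
        if T_m <= 0:
            raise ValueError(f"thickness must be > 0, got {T_m}")
        geom = dataclasses.replace(problem.geom, T=T_m / NM_TO_M)
        prob = dataclasses.replace(problem, geom=geom)
        t_i = imbibition_time(geom, prob.fluid)
        kwargs = dict(solver_kwargs)
        kwargs.setdefault("store_profiles", False)
        sol = solve_fick_1d(prob, **kwargs)
        interp = PchipInterpolator(sol.times, sol.center_ratio)
        target = prob.fill_fraction
        idx = int(np.searchsorted(sol.center_ratio, target))
        t_d = float(
            brentq(lambda t: interp(t) - target, sol.times[max(idx - 1, 0)],
                   sol.times[idx], rtol=1e-8)
        )
        rows.append(
            {
                "thickness_m": T_m,
                "t_imbibition_s": t_i,
                "t_diffusion_s": t_d,
                "center_ratio_final": float(sol.center_ratio[-1]),
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(sweep: pd.DataFrame, ax=None):
    """Log-log plot of t_i and t_D against tablet thickness."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(sweep["thickness_m"], sweep["t_imbibition_s"], "b*:",
              label=r"capillary imbibition $t_i$")
    ax.loglog(sweep["thickness_m"], sweep["t_diffusion_s"], "r*--",
              label=r"particle diffusion $t_D$")
    ax.set_xlabel("tablet thickness [m]")
    ax.set_ylabel("filling time [s]")
    ax.legend()
    return ax
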