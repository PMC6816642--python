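"""Inverse metering of suspended particles from nanoconfined-water self-diffusivity.

Water within a characteristic distance δ̄ of a solid–liquid interface (a pore
wall, a suspended nanoparticle or protein) has strongly reduced mobility. The
ensemble self-diffusion coefficient of water in such a system follows a linear
mixing law between the bulk value ``D_B`` and the fully confined value ``D_C``:

    D = D_B · [1 + (D_C/D_B − 1) · θ*],

where θ* is the *effective* fraction of the water volume that is nanoconfined.
The apparent fraction is θ = V_c/V_tot with V_c = Σᵢ SASᵢ·δ̄ᵢ summed over all
solid–liquid interfaces; because confinement shells of neighbouring interfaces
overlap, continuum percolation theory corrects it to θ* = 1 − exp(−θ).

Read backwards, a measured D in a pore of known geometry meters how many
particles the pore contains:

    n_p = (V_tot·θ − SAS_P·δ̄_P) / (SAS_p·δ̄_p),

with subscript ``P`` the pore wall and ``p`` one suspended particle. This
module implements the forward law, its inversion, the percolation correction,
concentration conversion and first-order (delta-method) uncertainty
propagation with a seeded Monte-Carlo cross-check.

Lengths are nm, areas nm², volumes nm³; diffusivities are m²/s as printed in
the experimental literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import NM3_TO_M3, AVOGADRO

__all__ = [
    "DiffusivityConstants",
    "Interface",
    "MeteringSystem",
    "MeteringResult",
    "Concentrations",
    "scaled_diffusivity",
    "invert_theta_star",
    "cpt_forward",
    "cpt_inverse",
    "confined_volume",
    "estimate_particle_count",
    "concentration",
    "propagate_uncertainty",
    "propagate_uncertainty_mc",
]


@dataclass(frozen=True)
class DiffusivityConstants:
    """Bulk and fully nanoconfined self-diffusion coefficients of water [m²/s].

    Defaults are for SPC/E-like water at 300 K: D_B = 2.60e-9 m²/s and a
    realistic fully confined value D_C = 0.39e-9 m²/s.
    """

    D_B: float = 2.60e-9
    D_C: float = 0.39e-9

    def __post_init__(self) -> None:
        if not (0.0 <= self.D_C < self.D_B):
            raise ValueError(
                f"require 0 <= D_C < D_B, got D_C={self.D_C}, D_B={self.D_B}"
            )


@dataclass(frozen=True)
class Interface:
    """One solid–liquid interface: SAS area [nm²], confinement length δ̄ [nm].

    ``count`` is the multiplicity of identical interfaces (number of particles;
    1 for the pore wall).
    """

    sas: float
    delta: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.sas <= 0:
            raise ValueError(f"sas must be > 0, got {self.sas}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")

    @property
    def confined_volume(self) -> float:
        """count · SAS · δ̄ [nm³]."""
        return self.count * self.sas * self.delta


@dataclass(frozen=True)
class MeteringSystem:
    """Pore wall + particle species + total water-accessible volume of the cell.

    ``V_tot`` and the SAS values refer to the same periodic analysis cell (the
    MD box in which SAS and δ̄ were calibrated); the macroscopic pore free
    volume used for concentrations is a different, deliberately distinct
    quantity (see :func:`concentration`).
    """

    pore_wall: Interface
    particle: Interface
    V_tot: float
    constants: DiffusivityConstants = field(default_factory=DiffusivityConstants)

    def __post_init__(self) -> None:
        if self.V_tot <= 0:
            raise ValueError(f"V_tot must be > 0, got {self.V_tot}")


@dataclass
class Concentrations:
    """Particle concentration in the macroscopic pore free volume."""

    number_per_nm3: float
    molar_mol_m3: float
    mass_g_m3: float | None = None


@dataclass
class MeteringResult:
    theta_star: float
    theta: float
    n_p: float
    n_p_sd: float = 0.0
    clamped: bool = False
    concentrations: Concentrations | None = None


def scaled_diffusivity(
    theta_star: float, constants: DiffusivityConstants | None = None
) -> float:
    """Forward scaling law: D(θ*) = D_B·[1 + (D_C/D_B − 1)·θ*] [m²/s].

    Linear and strictly decreasing in θ*, with D(0) = D_B and D(1) = D_C.
    """
    constants = constants or DiffusivityConstants()
    if not (0.0 <= theta_star <= 1.0):
        raise ValueError(f"theta_star must be in [0, 1], got {theta_star}")
    return constants.D_B * (1.0 + (constants.D_C / constants.D_B - 1.0) * theta_star)


def invert_theta_star(
    D: float, constants: DiffusivityConstants | None = None
) -> float:
    """Invert the scaling law: θ* = (D_B − D)/(D_B − D_C).

    Valid for D_C < D ≤ D_B; a D above bulk or at/below the full-confinement
    floor is unphysical for this model and raises.
    """
    constants = constants or DiffusivityConstants()
    if D > constants.D_B:
        raise ValueError(
            f"D={D} m²/s is faster than bulk water (D_B={constants.D_B}); "
            "theta_star would be negative"
        )
    if D <= constants.D_C:
        raise ValueError(
            f"D={D} m²/s is at/below the full-confinement floor "
            f"(D_C={constants.D_C}); theta_star would be >= 1"
        )
    return (constants.D_B - D) / (constants.D_B - constants.D_C)


def cpt_forward(theta: float) -> float:
    """Continuum-percolation overlap correction: θ* = 1 − exp(−θ).

    θ is the apparent (possibly > 1) confined fraction obtained by summing
    shell volumes as if they never overlapped; θ* is the fraction of space
    actually covered when the shells are placed at random (Poisson overlap).
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return -math.expm1(-theta)


def cpt_inverse(theta_star: float) -> float:
    """Exact inverse of :func:`cpt_forward`: θ = −ln(1 − θ*)."""
    if not (0.0 <= theta_star < 1.0):
        raise ValueError(
            f"theta_star must be in [0, 1) (confinement saturates at 1), "
            f"got {theta_star}"
        )
    return -math.log1p(-theta_star)


def confined_volume(interfaces: Sequence[Interface]) -> float:
    """Apparent confined water volume V_c = Σᵢ countᵢ·SASᵢ·δ̄ᵢ [nm³]."""
    if len(interfaces) == 0:
        raise ValueError("need at least one interface")
    return float(sum(i.confined_volume for i in interfaces))


def estimate_particle_count(
    D: float, system: MeteringSystem, apply_cpt: bool = True
) -> MeteringResult:
    """Meter the number of suspended particles from a measured diffusivity.

    Chains θ* = (D_B − D)/(D_B − D_C), θ = −ln(1 − θ*) (skipped when
    ``apply_cpt`` is False, which reproduces the dilute θ → 0 regime where
    θ* ≈ θ), then

        n_p = (V_tot·θ − SAS_P·δ̄_P) / (SAS_p·δ̄_p).

    A negative numerator (D consistent with an emptier pore than the bare wall)
    is clamped to n_p = 0 and flagged: it indicates measurement noise, not a
    negative particle count.
    """
    theta_star = invert_theta_star(D, system.constants)
    theta = cpt_inverse(theta_star) if apply_cpt else theta_star
    wall = system.pore_wall
    part = system.particle
    numerator = system.V_tot * theta - wall.sas * wall.delta
    n_p = numerator / (part.sas * part.delta)
    clamped = n_p < 0
    if clamped:
        n_p = 0.0
    return MeteringResult(theta_star=theta_star, theta=theta, n_p=n_p, clamped=clamped)


def concentration(
    n_p: float, d_P: float, T: float, molar_mass: float | None = None
) -> Concentrations:
    """Particle concentration in the free pore volume V_P = T·π·d_P²/4.

    ``d_P`` and ``T`` are the pore diameter and length (tablet thickness) in
    nm; ``molar_mass`` in g/mol additionally yields a mass concentration.
    """
    if d_P <= 0 or T <= 0:
        raise ValueError(f"pore geometry must be positive, got d_P={d_P}, T={T}")
    if n_p < 0:
        raise ValueError(f"n_p must be >= 0, got {n_p}")
    V_P = T * math.pi * d_P**2 / 4.0  # nm³
    c_num = n_p / V_P  # nm⁻³
    c_molar = c_num / NM3_TO_M3 / AVOGADRO  # mol/m³
    c_mass = c_molar * molar_mass if molar_mass is not None else None
    return Concentrations(
        number_per_nm3=c_num, molar_mol_m3=c_molar, mass_g_m3=c_mass
    )


def _delta_method_sd(
    D: float,
    D_sd: float,
    V_tot_sd: float,
    system: MeteringSystem,
    apply_cpt: bool = True,
) -> float:
    """First-order propagation of independent D and V_tot uncertainties.

    With B = SAS_p·δ̄_p and θ(D) = −ln(1 − θ*(D)):

        ∂n_p/∂D     = −V_tot / [B·(1 − θ*)·(D_B − D_C)]
        ∂n_p/∂V_tot = θ / B

    (without the CPT correction the 1/(1 − θ*) factor drops out).
    """
    c = system.constants
    theta_star = invert_theta_star(D, c)
    theta = cpt_inverse(theta_star) if apply_cpt else theta_star
    B = system.particle.sas * system.particle.delta
    dn_dD = -system.V_tot / (B * (c.D_B - c.D_C))
    if apply_cpt:
        dn_dD /= 1.0 - theta_star
    dn_dV = theta / B
    return math.hypot(dn_dD * D_sd, dn_dV * V_tot_sd)


def propagate_uncertainty(
    D: float,
    D_sd: float,
    V_tot_sd: float,
    system: MeteringSystem,
    apply_cpt: bool = True,
    n_draws: int = 10_000,
    seed: int = 0,
) -> MeteringResult:
    """Metering result with a 1-s.d. uncertainty on n_p.

    D and V_tot are treated as independent Gaussians. The primary estimate is
    the analytic delta method; when ±1 s.d. on D crosses the validity domain
    (D_C, D_B] the linearisation is unreliable and a truncated Monte-Carlo
    resampling (:func:`propagate_uncertainty_mc`) is used instead, with the
    result flagged as clamped.
    """
    if D_sd < 0 or V_tot_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    result = estimate_particle_count(D, system, apply_cpt=apply_cpt)
    crosses = (D + D_sd > system.constants.D_B) or (D - D_sd <= system.constants.D_C)
    if crosses and D_sd > 0:
        mean, sd = propagate_uncertainty_mc(
            D, D_sd, V_tot_sd, system, apply_cpt=apply_cpt,
            n_draws=n_draws, seed=seed,
        )
        result.n_p_sd = sd
        result.clamped = True
    else:
        result.n_p_sd = _delta_method_sd(D, D_sd, V_tot_sd, system, apply_cpt)
    return result


def propagate_uncertainty_mc(
    D: float,
    D_sd: float,
    V_tot_sd: float,
    system: MeteringSystem,
    apply_cpt: bool = True,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo resampling cross-check: returns (mean n_p, 1 s.d. of n_p).

    Draws D from a Gaussian truncated to the model's validity domain
    (D_C, D_B] and V_tot from a Gaussian truncated to positive values;
    negative particle counts are clamped to zero as in the point estimate.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    c = system.constants
    if D_sd > 0:
        lo = (c.D_C * (1 + 1e-12) - D) / D_sd
        hi = (c.D_B - D) / D_sd
        draws_D = stats.truncnorm.rvs(
            lo, hi, loc=D, scale=D_sd, size=n_draws, random_state=rng
        )
    else:
        draws_D = np.full(n_draws, D)
    if V_tot_sd > 0:
        lo_v = (0.0 - system.V_tot) / V_tot_sd
        draws_V = stats.truncnorm.rvs(
            lo_v, np.inf, loc=system.V_tot, scale=V_tot_sd,
            size=n_draws, random_state=rng,
        )
    else:
        draws_V = np.full(n_draws, system.V_tot)

    theta_star = (c.D_B - draws_D) / (c.D_B - c.D_C)
    theta = -np.log1p(-theta_star) if apply_cpt else theta_star
    wall = system.pore_wall
    part = system.particle
    n_p = (draws_V * theta - wall.sas * wall.delta) / (part.sas * part.delta)
    n_p = np.clip(n_p, 0.0, None)
    return float(n_p.mean()), float(n_p.std(ddof=1))
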