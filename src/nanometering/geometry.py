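"""Idealized geometric helpers for pores and particles.

Real SAS areas and confinement lengths δ̄ come from atomistic calibration and
are tabulated inputs; the closed forms here (probe-inflated sphere, lateral
cylinder surface, free pore volume, hydraulic radius) build system
descriptions when tabulated values are absent and anchor unit conventions.
All lengths nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PoreGeometry",
    "hydraulic_radius",
    "sphere_sas",
    "cylinder_pore_sas",
    "pore_free_volume",
]

#: Conventional probe radius [nm] for idealized SAS; same order as the pore
#: wall confinement length in calibrated tables. A convention of this package,
#: not a calibrated value.
DEFAULT_PROBE_RADIUS = 0.33


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore / tablet description.

    d_P : nominal pore diameter [nm] (= 2·r_0)
    T : pore length = tablet thickness [nm]
    phi_0 : nominal porosity of the tablet
    phi_i : effective porosity at the start of water uptake (defaults to
        phi_0: an initially dry tablet)
    tau : tortuosity (>= 1; 1 for straight through pores)
    d_w : water molecule diameter [nm]
    n_layers : number of adsorbed water layers immobilised on the pore wall
    """

    d_P: float
    T: float
    phi_0: float = 0.40
    phi_i: float | None = None
    tau: float = 1.0
    d_w: float = 0.275
    n_layers: int = 2

    def __post_init__(self) -> None:
        if self.d_P <= 0 or self.T <= 0:
            raise ValueError(f"d_P and T must be > 0, got {self.d_P}, {self.T}")
        if not (0.0 < self.phi_0 <= 1.0):
            raise ValueError(f"phi_0 must be in (0, 1], got {self.phi_0}")
        if self.phi_i is not None and not (0.0 < self.phi_i <= 1.0):
            raise ValueError(f"phi_i must be in (0, 1], got {self.phi_i}")
        if self.tau < 1.0:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.d_w < 0 or self.n_layers < 0:
            raise ValueError("d_w and n_layers must be >= 0")
        if self.d_P <= 2 * self.n_layers * self.d_w:
            raise ValueError(
                f"pore (d_P={self.d_P} nm) narrower than {self.n_layers} "
                f"adsorbed water layers of d_w={self.d_w} nm"
            )

    @property
    def r_0(self) -> float:
        """Nominal pore radius [nm]."""
        return self.d_P / 2.0

    @property
    def uptake_porosity(self) -> float:
        return self.phi_0 if self.phi_i is None else self.phi_i


def hydraulic_radius(geom: PoreGeometry) -> float:
    """r_h = r_0 − n_layers·d_w [nm]: the flowing cross-section radius.

    Water layers adsorbed on the capillary wall do not participate in the
    imbibition flow, shrinking the effective radius below nominal.
    """
    r_h = geom.r_0 - geom.n_layers * geom.d_w
    if r_h <= 0:
        raise ValueError(
            f"adsorbed layers ({geom.n_layers}x{geom.d_w} nm) fill the pore "
            f"radius {geom.r_0} nm"
        )
    return r_h


def sphere_sas(d_p: float, r_probe: float = DEFAULT_PROBE_RADIUS) -> float:
    """SAS of an idealized spherical particle: π·(d_p + 2·r_probe)² [nm²].

    The solvent-accessible surface is the sphere traced by the centre of a
    probe of radius ``r_probe`` rolled over the particle of diameter ``d_p``.
    """
    if d_p <= 0:
        raise ValueError(f"d_p must be > 0, got {d_p}")
    if r_probe < 0:
        raise ValueError(f"r_probe must be >= 0, got {r_probe}")
    return math.pi * (d_p + 2.0 * r_probe) ** 2


def cylinder_pore_sas(d_P: float, L: float) -> float:
    """Lateral surface of a through cylindrical pore segment: π·d_P·L [nm²]."""
    if d_P <= 0 or L < 0:
        raise ValueError(f"need d_P > 0 and L >= 0, got {d_P}, {L}")
    return math.pi * d_P * L


def pore_free_volume(d_P: float, T: float) -> float:
    """Free volume of a cylindrical through pore: V_P = T·π·d_P²/4 [nm³]."""
    if d_P <= 0 or T <= 0:
        raise ValueError(f"pore geometry must be positive, got {d_P}, {T}")
    return T * math.pi * d_P**2 / 4.0
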