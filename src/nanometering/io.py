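"""Table and configuration I/O for the metering protocol.

System tables are CSV/TSV with unit-suffixed column headers (``D_m2s``,
``V_tot_nm3``, ...) to prevent silent unit mistakes — the field's literature
mixes nm and SI freely. The packaged ``table1.csv`` fixture is the reference
benchmark set of twelve metered systems (iron-oxide nanoparticles and two
proteins in silica nanopores) with their published estimates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .filling import FillingProblem, FluidProperties
from .geometry import PoreGeometry
from .metering import (
    DiffusivityConstants,
    Interface,
    MeteringSystem,
    estimate_particle_count,
    propagate_uncertainty,
)
from .units import NM_TO_M

__all__ = [
    "TABLE_COLUMNS",
    "load_table1",
    "read_system_table",
    "write_table",
    "meter_table",
    "load_constants",
    "load_filling_config",
    "packaged_filling_config",
]

#: Required columns of a metering system table.
TABLE_COLUMNS = [
    "MOL",
    "D_m2s",
    "V_tot_nm3",
    "delta_p_nm",
    "SAS_p_nm2",
    "delta_P_nm",
    "SAS_P_nm2",
]

#: Optional columns carried through when present.
OPTIONAL_COLUMNS = [
    "d_P_nm", "d_p_nm", "n_p_o", "theta_star", "theta", "n_p_e",
    "D_sd_m2s", "V_tot_sd_nm3",
]


def _data_path(name: str):
    return resources.files("nanometering").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """The packaged twelve-row benchmark table."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return pd.read_csv(p)


def read_system_table(path: str | Path) -> pd.DataFrame:
    """Read a system table (CSV, or TSV for .tsv/.txt) and validate columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


def meter_table(
    df: pd.DataFrame,
    constants: DiffusivityConstants | None = None,
    apply_cpt: bool = True,
) -> pd.DataFrame:
    """Run the metering inversion on every row of a system table.

    Adds ``theta_star_est``, ``theta_est``, ``n_p_est`` and ``flag`` columns
    (plus ``n_p_sd`` when ``D_sd_m2s``/``V_tot_sd_nm3`` uncertainty columns
    are present). Rows whose D lies outside the model's validity domain are
    flagged ``out_of_domain`` and retained with NaN estimates; the other rows
    are unaffected.
    """
    constants = constants or DiffusivityConstants()
    out = df.copy()
    has_sd = "D_sd_m2s" in df.columns or "V_tot_sd_nm3" in df.columns
    ts, th, n_est, n_sd, flags = [], [], [], [], []
    for _, row in df.iterrows():
        system = MeteringSystem(
            pore_wall=Interface(sas=row["SAS_P_nm2"], delta=row["delta_P_nm"]),
            particle=Interface(sas=row["SAS_p_nm2"], delta=row["delta_p_nm"]),
            V_tot=row["V_tot_nm3"],
            constants=constants,
        )
        try:
            if has_sd:
                d_sd = row.get("D_sd_m2s", 0.0)
                v_sd = row.get("V_tot_sd_nm3", 0.0)
                res = propagate_uncertainty(
                    row["D_m2s"],
                    float(d_sd) if pd.notna(d_sd) else 0.0,
                    float(v_sd) if pd.notna(v_sd) else 0.0,
                    system,
                    apply_cpt=apply_cpt,
                )
            else:
                res = estimate_particle_count(
                    row["D_m2s"], system, apply_cpt=apply_cpt
                )
            ts.append(res.theta_star)
            th.append(res.theta)
            n_est.append(res.n_p)
            n_sd.append(res.n_p_sd)
            flags.append("clamped" if res.clamped else "ok")
        except ValueError:
            ts.append(np.nan)
            th.append(np.nan)
            n_est.append(np.nan)
            n_sd.append(np.nan)
            flags.append("out_of_domain")
    out["theta_star_est"] = ts
    out["theta_est"] = th
    out["n_p_est"] = n_est
    if has_sd:
        out["n_p_sd"] = n_sd
    out["flag"] = flags
    return out


def _as_float(value) -> float:
    # YAML 1.1 resolves "1.0e6" (no exponent sign) as a string; coerce.
    return float(value)


def load_constants(path: str | Path) -> DiffusivityConstants:
    """Diffusivity constants from a YAML mapping with keys D_B_m2s, D_C_m2s."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    if "D_B_m2s" in cfg:
        kwargs["D_B"] = _as_float(cfg["D_B_m2s"])
    if "D_C_m2s" in cfg:
        kwargs["D_C"] = _as_float(cfg["D_C_m2s"])
    return DiffusivityConstants(**kwargs)


def _filling_from_dict(cfg: dict) -> FillingProblem:
    pore = cfg.get("pore", {})
    fluid = cfg.get("fluid", {})
    particle = cfg.get("particle", {})
    geom = PoreGeometry(
        d_P=_as_float(pore.get("d_P_nm", 11.04)),
        T=_as_float(pore.get("thickness_m", 1e-3)) / NM_TO_M
        if "thickness_m" in pore
        else _as_float(pore.get("thickness_nm", 1e6)),
        phi_0=_as_float(pore.get("porosity", 0.40)),
        tau=_as_float(pore.get("tortuosity", 1.0)),
        d_w=_as_float(pore.get("d_w_nm", 0.275)),
        n_layers=int(pore.get("n_adsorbed_layers", 2)),
    )
    fl = FluidProperties(
        surface_tension=_as_float(fluid.get("surface_tension_N_m", 0.072)),
        viscosity=_as_float(fluid.get("viscosity_Pa_s", 1.0e-3)),
        contact_angle=_as_float(fluid.get("contact_angle_rad", 0.0)),
    )
    return FillingProblem(
        geom=geom,
        D_p=_as_float(particle["diffusivity_m2_s"]),
        fluid=fl,
        c_b=_as_float(particle.get("bulk_concentration_mol_m3", 3.4)),
        fill_fraction=_as_float(cfg.get("fill_fraction", 0.95)),
    )


def load_filling_config(path: str | Path) -> FillingProblem:
    """Build a :class:`FillingProblem` from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "particle" not in cfg:
        raise ValueError(f"{path}: not a filling config (needs a 'particle' block)")
    return _filling_from_dict(cfg)


def packaged_filling_config(name: str) -> FillingProblem:
    """Load one of the shipped example configs: 'lysozyme' or 'doxorubicin'."""
    fname = {"lysozyme": "lysozyme_filling.yaml",
             "doxorubicin": "doxorubicin_filling.yaml"}.get(name)
    if fname is None:
        raise ValueError(f"unknown packaged config {name!r}")
    with resources.as_file(_data_path(fname)) as p:
        return load_filling_config(p)
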