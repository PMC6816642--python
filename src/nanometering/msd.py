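"""Self-diffusion coefficient estimation from tracer trajectories.

The Einstein relation for 3D Brownian motion, MSD(τ) = 6·D·τ, turns the slope
of the ensemble mean-square displacement against lag time into a diffusivity.
This module provides:

* a :class:`Trajectory` container (uniformly sampled, multi-tracer),
* an FFT-accelerated time-origin-averaged MSD (every origin, stride 1),
* a weighted least-squares fit of the MSD window with a 1-s.d. uncertainty,
* a block-wise convergence monitor mirroring the usual production-run check
  (±10% fluctuation of per-block D around its moving average),
* a seeded synthetic Brownian generator standing in for MD output,
* plain-text trajectory I/O.

Internal units are nm and ps (so D is fitted in nm²/ps and converted to m²/s
at the boundary: 1 nm²/ps = 1e-6 m²/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .units import NM2_PER_PS_TO_M2_PER_S

__all__ = [
    "Trajectory",
    "DiffusivityEstimate",
    "ConvergenceReport",
    "generate_brownian",
    "msd_curve",
    "fit_diffusivity",
    "estimate_diffusivity",
    "convergence_monitor",
    "load_trajectory",
    "save_trajectory",
]


@dataclass
class Trajectory:
    """Uniformly sampled positions of a tracer ensemble.

    times : shape (n_frames,), ps, strictly increasing, uniform spacing
    positions : shape (n_tracers, n_frames, 3), nm
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("times must be 1D with at least 2 frames")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_tracers, n_frames, 3)")
        if self.positions.shape[1] != len(self.times):
            raise ValueError("positions and times disagree on frame count")
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one tracer")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=0.0):
            raise ValueError("non-uniform sampling interval")
        if not (np.isfinite(self.times).all() and np.isfinite(self.positions).all()):
            raise ValueError("non-finite values in trajectory")

    @property
    def n_tracers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Sampling interval [ps]."""
        return float(self.times[1] - self.times[0])


@dataclass
class DiffusivityEstimate:
    """D and its 1-s.d. uncertainty [m²/s], fit window [ps], convergence flag.

    ``converged`` is False when the fitted slope was negative (clamped to 0)
    or when the MSD in the window is not diffusive (log-log slope far from 1,
    e.g. ballistic motion).
    """

    D: float
    D_sd: float
    window: tuple[float, float]
    converged: bool = True


def generate_brownian(
    n_tracers: int,
    n_frames: int,
    dt: float = 1.0,
    D: float = 2.6e-9,
    seed: int = 0,
) -> Trajectory:
    """Synthetic free-Brownian tracer ensemble (test stand-in for MD output).

    Independent Gaussian increments per axis with variance 2·D·dt; ``dt`` in
    ps, ``D`` in m²/s. Bit-reproducible for a fixed seed.
    """
    if n_tracers < 1 or n_frames < 2:
        raise ValueError("need n_tracers >= 1 and n_frames >= 2")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    rng = np.random.default_rng(seed)
    d_nmps = D / NM2_PER_PS_TO_M2_PER_S
    sigma = np.sqrt(2.0 * d_nmps * dt)
    steps = rng.normal(0.0, sigma, size=(n_tracers, n_frames - 1, 3)) if sigma > 0 \
        else np.zeros((n_tracers, n_frames - 1, 3))
    positions = np.concatenate(
        [np.zeros((n_tracers, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return Trajectory(times=np.arange(n_frames) * dt, positions=positions)


def _msd_fft(positions: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD for every lag, per tracer.

    positions : (n_tracers, N, 3) -> msd : (n_tracers, N)

    Uses the Wiener–Khinchin decomposition MSD(m) = (S1(m) − 2·S2(m))/(N − m)
    with S2 the positional autocorrelation evaluated by FFT and S1 a running
    sum of squared norms; O(N log N) per tracer instead of O(N²).
    """
    n_tracers, N, _ = positions.shape
    nfft = next_fast_len(2 * N)
    # S2 summed over the three axes
    f = rfft(positions, n=nfft, axis=1)
    s2 = irfft((f * f.conj()).real.sum(axis=2), n=nfft, axis=1)[:, :N]
    d_sq = (positions**2).sum(axis=2)  # (n_tracers, N)
    q = 2.0 * d_sq.sum(axis=1, keepdims=True)
    head = np.concatenate(
        [np.zeros((n_tracers, 1)), np.cumsum(d_sq, axis=1)[:, :-1]], axis=1
    )
    tail = np.concatenate(
        [np.zeros((n_tracers, 1)), np.cumsum(d_sq[:, ::-1], axis=1)[:, :-1]], axis=1
    )
    s1 = q - head - tail
    counts = N - np.arange(N)
    return (s1 - 2.0 * s2) / counts


def msd_curve(
    traj: Trajectory,
    max_lag_fraction: float = 0.5,
    per_tracer: bool = False,
    chunk: int = 256,
):
    """Ensemble MSD against lag time.

    MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ averaged over every time origin (stride 1)
    and every tracer. Returns ``(lags_ps, msd_nm2)``, plus the per-tracer MSD
    matrix when ``per_tracer`` is True. Lags run from 0 to
    ``max_lag_fraction`` of the trajectory length.
    """
    if not (0.0 < max_lag_fraction <= 1.0):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    N = traj.n_frames
    n_lags = max(2, int(max_lag_fraction * (N - 1)) + 1)
    parts = [
        _msd_fft(traj.positions[i : i + chunk])
        for i in range(0, traj.n_tracers, chunk)
    ]
    msd_pt = np.concatenate(parts, axis=0)[:, :n_lags]
    msd_pt = np.clip(msd_pt, 0.0, None)  # FFT round-off can leave -1e-16 at lag 0
    lags = np.arange(n_lags) * traj.dt
    msd = msd_pt.mean(axis=0)
    if per_tracer:
        return lags, msd, msd_pt
    return lags, msd


def _wls_slope(lags: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS fit of y = a + b·lag; returns (b, se_b).

    ``y`` may be (n_points,) or (n_series, n_points); the standard error is
    the conventional WLS slope standard error from the residual scatter.
    """
    X = np.column_stack([np.ones_like(lags), lags])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = np.atleast_2d(y) * sw
    beta, *_ = np.linalg.lstsq(Xw, yw.T, rcond=None)
    resid = yw.T - Xw @ beta
    dof = max(len(lags) - 2, 1)
    s2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se_b = np.sqrt(s2 * xtx_inv[1, 1])
    if np.ndim(y) == 1:
        return float(beta[1, 0]), float(se_b[0])
    return beta[1], se_b


def _diffusive_exponent(lags: np.ndarray, msd: np.ndarray) -> float:
    """Log-log slope of the MSD in the window; 1 for diffusion, 2 ballistic."""
    mask = (lags > 0) & (msd > 0)
    if mask.sum() < 3:
        return 1.0
    coef = np.polyfit(np.log(lags[mask]), np.log(msd[mask]), 1)
    return float(coef[0])


def fit_diffusivity(
    lags: np.ndarray,
    msd: np.ndarray,
    weights: np.ndarray | None = None,
) -> DiffusivityEstimate:
    """Fit D = slope/6 from an MSD curve by weighted least squares.

    ``lags`` in ps, ``msd`` in nm²; ``weights`` default to uniform (pass the
    per-lag origin counts N − m to down-weight the noisier long lags). The
    1-s.d. uncertainty is the WLS slope standard error divided by 6. A
    negative fitted slope is clamped to D = 0 and flagged; a clearly
    non-diffusive window (log-log exponent outside [0.7, 1.3]) is flagged too.
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if len(lags) < 3:
        raise ValueError("need at least 3 MSD points to fit")
    if weights is None:
        weights = np.ones_like(lags)
    slope, se = _wls_slope(lags, msd, np.asarray(weights, dtype=float))
    D = slope / 6.0 * NM2_PER_PS_TO_M2_PER_S
    D_sd = se / 6.0 * NM2_PER_PS_TO_M2_PER_S
    converged = True
    if D < 0:
        D = 0.0
        converged = False
    elif msd.max() > 0:
        converged = 0.7 <= _diffusive_exponent(lags, msd) <= 1.3
    return DiffusivityEstimate(
        D=D, D_sd=D_sd, window=(float(lags[0]), float(lags[-1])),
        converged=converged,
    )


def estimate_diffusivity(
    traj: Trajectory, window: tuple[float, float] = (0.1, 0.5)
) -> DiffusivityEstimate:
    """Estimate D ± 1 s.d. from a trajectory.

    The fit window covers lags between ``window[0]`` and ``window[1]`` of the
    trajectory duration (short lags are ballistic/correlated in real MD, long
    lags have few independent origins), weighted by the per-lag origin count.
    The point estimate is the WLS slope of the ensemble MSD; the uncertainty
    treats tracers as equivalent and independent — it is the standard error
    over per-tracer slope estimates — except for single-tracer input, where
    the WLS slope error is all there is.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid window {window}")
    lags, msd, msd_pt = msd_curve(traj, max_lag_fraction=hi, per_tracer=True)
    duration = traj.times[-1] - traj.times[0]
    mask = (lags >= lo * duration) & (lags <= hi * duration)
    if mask.sum() < 3:
        raise ValueError("window leaves fewer than 3 MSD points")
    w = (traj.n_frames - np.arange(len(lags)))[mask].astype(float)
    est = fit_diffusivity(lags[mask], msd[mask], weights=w)
    if traj.n_tracers > 1:
        slopes, _ = _wls_slope(lags[mask], msd_pt[:, mask], w)
        d_i = slopes / 6.0 * NM2_PER_PS_TO_M2_PER_S
        est.D_sd = float(d_i.std(ddof=1) / np.sqrt(traj.n_tracers))
    return est


@dataclass
class ConvergenceReport:
    """Per-block diffusivity estimates and the moving-average convergence flag."""

    block_times: np.ndarray  # end time of each block [ps]
    block_D: np.ndarray  # per-block D [m²/s]
    moving_average: np.ndarray
    converged: bool


def convergence_monitor(
    traj: Trajectory,
    block: float = 100.0,
    tolerance: float = 0.10,
    n_recent: int = 3,
    window: tuple[float, float] = (0.1, 0.5),
) -> ConvergenceReport:
    """Steady-state check on a production run, block by block.

    The trajectory is cut into consecutive blocks of ``block`` ps, D is
    estimated within each block, and the run is declared converged when the
    last ``n_recent`` block estimates all lie within ``tolerance`` (±10% by
    default) of the running moving average.
    """
    frames_per_block = int(round(block / traj.dt))
    if frames_per_block < 4:
        raise ValueError("block shorter than 4 frames")
    n_blocks = traj.n_frames // frames_per_block
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    block_D, block_t = [], []
    for b in range(n_blocks):
        sl = slice(b * frames_per_block, (b + 1) * frames_per_block)
        sub = Trajectory(times=traj.times[sl], positions=traj.positions[:, sl])
        block_D.append(estimate_diffusivity(sub, window=window).D)
        block_t.append(traj.times[sl][-1])
    block_D = np.asarray(block_D)
    moving = np.cumsum(block_D) / np.arange(1, n_blocks + 1)
    recent = block_D[-n_recent:]
    avg = moving[-1]
    converged = bool(np.all(np.abs(recent - avg) <= tolerance * avg)) if avg > 0 \
        else bool(np.all(recent == 0))
    return ConvergenceReport(
        block_times=np.asarray(block_t),
        block_D=block_D,
        moving_average=moving,
        converged=converged,
    )


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as whitespace-delimited text.

    One row per frame: time [ps] followed by x, y, z [nm] for each tracer.
    """
    n = traj.n_tracers
    data = np.column_stack(
        [traj.times] + [traj.positions[i] for i in range(n)]
    )
    header = "t_ps " + " ".join(f"x{i} y{i} z{i}" for i in range(n))
    np.savetxt(path, data, header=header)


def load_trajectory(path: str | Path) -> Trajectory:
    """Read a whitespace- or comma-delimited text trajectory.

    Expects a time column followed by 3 coordinate columns per tracer; raises
    a ValueError naming the offending line on malformed input.
    """
    path = Path(path)
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if n_cols is None:
                n_cols = len(fields)
                if (n_cols - 1) % 3 != 0 or n_cols < 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 1 + 3·n_tracers columns, "
                        f"got {n_cols}"
                    )
            elif len(fields) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows)
    n_tracers = (data.shape[1] - 1) // 3
    positions = data[:, 1:].reshape(len(rows), n_tracers, 3).transpose(1, 0, 2)
    return Trajectory(times=data[:, 0], positions=positions)
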