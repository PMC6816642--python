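# Methods

## Metering model

The package treats the water in a loaded nanopore as a two-state ensemble:
bulk-like water diffusing at `D_B` and nanoconfined water at `D_C`, mixed
linearly by the effective confined volume fraction θ*:

    D(θ*) = D_B·[1 + (D_C/D_B − 1)·θ*].

Defaults `D_B = 2.60e-9 m²/s` and `D_C = 0.39e-9 m²/s` correspond to SPC/E-like
water at 300 K; both are overridable through `DiffusivityConstants` or a YAML
config, e.g. to rescale to another temperature. The model is valid for
`D_C < D ≤ D_B`; measurements outside that interval are rejected as
out-of-domain rather than extrapolated (per-row in table processing, so one
bad measurement never poisons a batch).

The apparent confined fraction sums per-interface confinement shells,
`θ = Σᵢ countᵢ·SASᵢ·δ̄ᵢ / V_tot`. SAS and δ̄ are *calibrated* quantities taken
from atomistic simulation; they are inputs here, not outputs (the idealized
sphere/cylinder helpers in `geometry` are conventions for building test
systems, with a default probe radius of 0.33 nm chosen to match the order of
the tabulated wall confinement length). Because shells overlap, θ is only
apparent; continuum percolation theory (CPT) maps it to the covered fraction
under the assumption of Poisson-random shell placement, `θ* = 1 − exp(−θ)`.
The corrected θ* is used inside the scaling law by default; `apply_cpt=False`
exposes the uncorrected variant for the dilute regime θ → 0 where the two
coincide.

The inversion chain is analytic throughout: `θ* = (D_B − D)/(D_B − D_C)`,
`θ = −ln(1 − θ*)`, `n_p = (V_tot·θ − SAS_P·δ̄_P)/(SAS_p·δ̄_p)`. A negative
numerator (a pore measured emptier than its bare wall) is clamped to zero and
flagged instead of raised: it is the signature of measurement noise near the
empty-pore floor, not an invalid input. Two distinct volumes appear by
design: `V_tot` is the water-accessible volume of the periodic analysis cell
in which SAS/δ̄ were calibrated, while the concentration step uses the
macroscopic free pore volume `V_P = T·π·d_P²/4` of the cylindrical through
pore.

Units: lengths nm, areas nm², volumes nm³, diffusivities m²/s (as printed in
the experimental literature); conversions are centralized in `units.py`.
Number concentrations convert to mol/m³ through the Avogadro constant
(1 nm⁻³ = 1e27/6.02214076e23 mol/m³ ≈ 1660.6 mol/m³).

### Uncertainty

The measured inputs carry 1-s.d. uncertainties on D (from the MSD fit) and on
V_tot. They are treated as independent Gaussians and propagated first order
(delta method):

    ∂n_p/∂D = −V_tot / [SAS_p·δ̄_p·(1 − θ*)·(D_B − D_C)],
    ∂n_p/∂V_tot = θ / (SAS_p·δ̄_p).

A seeded Monte-Carlo resampler (default 10⁴ draws) cross-checks the analytic
result; the two agree within a few percent for realistic uncertainty levels.
When ±1 s.d. on D crosses the validity domain the linearisation is biased, so
the implementation switches to the Monte-Carlo path with the sampling
distribution truncated to `(D_C, D_B]` and flags the result. Whether the
analytic or sampling route is "the" reference is an open design choice; the
delta method is primary here because it is deterministic and exposes the
sensitivities.

## Filling models

Capillary imbibition uses the sharp-front Darcy form of Lucas–Washburn:
`t_i = h²·φᵢ·μ/(2·K·Δp)` with permeability `K = r_h⁴·φ₀/(8·r₀²·τ)` and
capillary pressure `Δp = 2σ·cos ϑ/r_h`. The hydraulic radius subtracts
`n_layers` (default 2) adsorbed water layers of diameter 0.275 nm from the
nominal radius. Fluid defaults are bulk water at 300 K on silica: σ = 0.072
N/m, μ = 1e-3 Pa·s, ϑ = 0. Suspended particles are assumed not to perturb
imbibition — valid for dilute suspensions with particle/pore size ratios
below ~10%; no correction is attempted beyond that.

Particle entry into the hydrated pores is one-dimensional Fickian diffusion,
`φ₀·∂c/∂t = D_e·∂²c/∂x²` with `D_e = φ₀·D_p/τ`, both faces of the tablet
held at the bulk concentration and zero initial concentration inside. The
porosity cancels in c/c_b (the curve depends only on `D_p/τ`), which the test
suite asserts numerically. The filling time `t_D` is the first time the
centre concentration reaches `fill_fraction` (default 0.95) of bulk.

### Numerics

The solver works in dimensionless variables (ξ = x/T, s = (D_p/τ)t/T²) with
Crank–Nicolson time stepping on a uniform grid: 201 nodes and a step of
1.25e-4 in s by default, preceded by four backward-Euler half-steps
(Rannacher smoothing) that damp the oscillations the initial corner
discontinuity at the boundaries would otherwise excite in a trapezoidal
scheme. Against the analytic Fourier-series slab solution the centre
concentration is accurate to ~3e-5 absolute over Fo ∈ [0.01, 2] — the
contract asserted in the tests is 5e-3. `t_D` is located on the stored,
monotone centre-ratio curve by monotone PCHIP interpolation and Brent
root-finding (relative tolerance 1e-8, far tighter than the 0.1% that
matters). The discretization is an implementation detail; equivalence with
the series solution at the stated tolerance is the contract.

`t_D ∝ T²` exactly in this model, and for the lysozyme configuration
(D_p = 11.08e-11 m²/s) the 1 mm tablet gives t_D ≈ 2960 s against
t_i ≈ 6.9 s — diffusion is slower than imbibition by roughly two orders of
magnitude at every thickness.

## MSD estimation

`MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩` is averaged over every time origin (stride 1)
and tracer, computed per tracer in O(N log N) by the Wiener–Khinchin
decomposition (FFT autocorrelation); a brute-force O(N²) implementation in
the test suite pins the algorithm. The fit window defaults to lags between
10% and 50% of the trajectory duration: in real MD data short lags are
ballistic/correlated and long lags have too few independent origins. Weighted
least squares with weights equal to the per-lag origin count gives
`D = slope/6`. The reported 1-s.d. uncertainty treats tracers as equivalent
and independent — it is the standard error of per-tracer slope estimates —
because MSD points within one tracer are strongly correlated across lags and
a naive regression standard error would not be a valid sampling uncertainty;
for a single tracer the WLS slope error is reported instead. A log-log
exponent check (accept 0.7–1.3) flags non-diffusive windows such as ballistic
motion, and a negative fitted slope clamps to D = 0 with a flag.

The convergence monitor mirrors the usual production-run criterion: D is
estimated in consecutive 100 ps blocks and the run is converged when the last
three block estimates lie within ±10% of the running moving average.

The synthetic generator draws independent Gaussian increments with per-axis
variance 2·D·dt. It emulates free, homogeneous, uncorrelated Brownian
tracers — it has no ballistic regime, no hydrodynamic or confinement
correlations, and no heterogeneity between tracers — so passing parameter
recovery shows estimator correctness on ideal diffusive data, not robustness
to the short-time physics of real MD trajectories (which the fit window is
designed to avoid).

## Monte-Carlo validation of the percolation correction

Scenes are explicit geometric embodiments of a loaded pore: a cylinder of
diameter d_P with a wall shell of thickness δ_P, loaded with n hard spheres
(diameter d_p, shell δ_p) placed by sequential rejection sampling (uniform,
non-overlapping, periodic minimum-image along the axis to mirror the periodic
analysis cell; placement refuses packing fractions ≥ 0.3 and aborts after
10⁵ consecutive rejections). Uniform points sample the water region (inside
the cylinder, outside the solid cores); the covered fraction counts points
within δ_P of the wall or δ_p of a particle surface, with binomial standard
error.

θ for a scene uses exact shell volumes — the wall annulus and the spherical
shells — over the water volume, not the SAS·δ̄ product: the sampler tests the
overlap formula, and for nm-scale spheres the calibrated SAS·δ̄ differs from
the true geometric shell volume by a factor approaching 2 (δ̄ is a
model parameter fitted to atomistic data, not a literal shell thickness).

Agreement: in the dilute regime (θ ≤ 0.05) the sampled fraction tracks θ
itself within 0.01. At higher loadings the hard-sphere scenes *systematically
exceed* the CPT prediction — by up to ~0.08 near θ ≈ 0.8–2 — for three
reasons documented rather than suppressed: core exclusion spreads shells
apart and enlarges their union relative to Poisson placement; shells never
swallow other particles' cores (the shell outer radius is below the
hard-core distance), so the full shell volume is always water; and the wall
annulus is deterministic, not random. A penetrable-placement diagnostic
brings the sampler within ~0.01–0.03 of CPT (the remainder being
finite-pore boundary effects), confirming the residual is physics of the
hard-sphere scene, not sampler error. Consequence for the metering protocol:
in strongly loaded pores the Poisson overlap correction is an approximation
whose sign is known (it over-corrects θ* downward relative to a hard-sphere
reality).

## Problem sizes and determinism

Every stochastic component (generator, placement, sampling, resampling) takes
an explicit seed and is bit-reproducible. Default study sizes — 1000 tracers
× 1000 frames for MSD recovery, 2e5 sample points per Monte-Carlo scene, 10⁴
uncertainty draws, 201-node/1.25e-4-step Fick solves — were chosen so the
statistical error of each check sits well below the tolerance it is tested
against while a full validation run stays interactive on a laptop.

## Known limitations

* SAS and δ̄ must come from external calibration; the idealized helpers are
  conventions, not substitutes.
* The scaling-law inversion saturates: measurements near D_C imply θ* → 1 and
  the particle count diverges; near D_B the count clamps at zero. Useful
  resolution lives roughly in θ* ∈ [0.2, 0.8]. Numerically, 1 − exp(−θ)
  rounds to exactly 1 in double precision above θ ≈ 36.
* The CPT correction assumes Poisson shells; hard-sphere order biases it at
  high loading (see above).
* In-pore particle diffusivity is taken equal to bulk `D_p`; hindered
  diffusion in nanopores can be substantially slower, so `t_D` is a lower
  bound to be refined case by case.
* No sonication/centrifugation-assisted filling, no particle–wall
  interaction corrections, no pore clogging model.
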