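"""Check the percolation overlap correction by direct geometric sampling.

Builds cylindrical-pore scenes loaded with hard spheres carrying confinement
shells, measures the covered fraction of the water volume by Monte-Carlo
sampling, and compares it with the continuum-percolation prediction
θ* = 1 − exp(−θ). Hard-sphere exclusion makes real shell unions cover
slightly more than the Poisson assumption — the discrepancy column makes
that residual visible instead of hiding it.
"""

from nanometering import SceneSpec, cpt_agreement_report

base = SceneSpec(d_P=11.04, L=5.6, delta_P=0.33, d_p=1.27, delta_p=0.46, seed=11)
report = cpt_agreement_report(base, [0, 8, 20, 40, 66], n_samples=200_000, seed=42)
print(report.round(4).to_string(index=False))
print(
    "\ntheta: apparent shell fraction (overlaps double-counted); "
    "theta_star_mc: sampled\ncovered fraction; cpt: 1 - exp(-theta). The "
    "discrepancy grows with loading as\nhard-sphere order departs from the "
    "Poisson-shell idealization."
)
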