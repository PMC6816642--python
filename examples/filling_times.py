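"""How long does a dry metering tablet take to fill?

Water imbibes the nanopores by capillarity in seconds; the suspended
particles then enter by Fickian diffusion, which dominates the total filling
time by about two orders of magnitude.
"""

from nanometering import (
    diffusion_filling_time,
    imbibition_time,
    packaged_filling_config,
)

for name in ["lysozyme", "doxorubicin"]:
    problem = packaged_filling_config(name)
    t_i = imbibition_time(problem.geom, problem.fluid)
    t_d = diffusion_filling_time(problem)
    print(
        f"{name:12s} tablet {problem.thickness_m * 1e3:5.2f} mm: "
        f"water imbibition t_i = {t_i:6.2f} s, "
        f"particle diffusion t_D = {t_d:7.1f} s "
        f"(centre at {problem.fill_fraction:.0%} of bulk), "
        f"t_D/t_i = {t_d / t_i:5.0f}"
    )

print(
    "\nt_i is the Lucas-Washburn/Darcy time for water to wet the full "
    "thickness;\nt_D the time for the particle concentration at the tablet "
    "centre to reach 95%\nof the bulk value — the rate-limiting step of the "
    "metering protocol."
)
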