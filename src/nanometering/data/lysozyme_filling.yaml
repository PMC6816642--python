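# Lysozyme (hen egg-white, 1AKI) diffusing into a 1 mm silica tablet:
# ~1% weight-fraction solution, straight 11.04 nm pores, porosity 40%.
pore:
  d_P_nm: 11.04
  thickness_m: 1.0e-3
  porosity: 0.40
  tortuosity: 1.0
  d_w_nm: 0.275
  n_adsorbed_layers: 2
fluid:
  surface_tension_N_m: 0.072
  viscosity_Pa_s: 1.0e-3
  contact_angle_rad: 0.0
particle:
  diffusivity_m2_s: 11.08e-11
  bulk_concentration_mol_m3: 3.4
fill_fraction: 0.95
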