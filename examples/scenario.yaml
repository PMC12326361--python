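# Shake-flask scenario: weak acid (naproxen-like), 1:3 octanol:water,
# four overall concentrations straddling the OECD 0.01 mol/L ceiling.
solute:
  name: naproxen
  ionization_class: acid
  pka: 4.18
system:
  volume_org: 0.25    # L
  volume_aq: 0.75     # L
  P_neutral_0: 2187.8 # 10**3.34, infinite-dilution neutral-species c_org/c_aq
  conc_slope_s: 0.0   # L/mol, concentration dependence of log10 P_neutral
  P_ion: 0.0          # charged species confined to the aqueous phase
  temperature: 25.0   # degC
grid: [1.0e-3, 2.5e-3, 5.0e-3, 1.0e-2]  # overall concentrations, mol/L
noise:
  rel_conc_sigma: 0.05  # lognormal sigma on both phase concentrations
  ph_sigma: 0.02        # Gaussian sigma on measured pH
  seed: 1
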