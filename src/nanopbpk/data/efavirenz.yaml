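# Efavirenz compound record. Units: mw g/mol, diff_coeff cm^2/s, density g/mL,
# solubilities mg/mL, interfacial_tension J/m^2, peff cm/s, vmax mg/s (whole
# organ), km mg/L, kaff mg/mL/mM, radii um.
name: efavirenz
mw: 315.67
logp: 4.6
pka: 10.2
pka_type: acid
diff_coeff: 7.473e-06
density: 1.395
sol_aq: 0.009
sol_aq_ph: 6.97
sol_fassif: 0.182
sol_fessif: 0.847
solubilization_factor: 4342.8
bile_sr: 357000.0
interfacial_tension: 0.02327
nano_factor: 1.381
nano_radius_threshold: 1.0
fup:
  rat: 0.0058
  human: 0.0022
bp_ratio:
  rat: 0.92
  human: 0.74
peff:
  rat: 1.658e-04
  human: 7.385e-04
enzymes:
  rat:
  - {enzyme: CYP2B2, site: liver, vmax: 0.0517, km: 0.9035}
  - {enzyme: CYP3A9, site: liver, vmax: 0.0318, km: 0.9278}
  - {enzyme: CYP3A9, site: gut, vmax: 0.00044, km: 0.9278}
  human:
  - {enzyme: CYP2B6, site: liver, vmax: 0.05, km: 3.914}
  - {enzyme: CYP3A4, site: liver, vmax: 0.00083, km: 6.314}
  - {enzyme: CYP3A4, site: gut, vmax: 0.00044, km: 6.314}
kaff: 0.0755
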