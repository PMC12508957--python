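# Fasted rat whole-body physiology, reference body weight 0.35 kg.
# Tissue volumes/flows start from standard rodent tables; the lipid depot
# volumes (adipose, yellow marrow) and the hepatic blood flow are effective
# parameters calibrated once against the model's systemic outputs (see
# docs/methods.md) and then frozen.  Kp column: Poulin-Theil values.
# Units: volumes L (GI lumen mL), flows L/h, gfr L/h, transit h, bile mM,
# sa_v 1/cm.
species: rat
reference_body_weight: 0.35
venous_volume: 0.0173
arterial_volume: 0.0086
plasma_fraction: 0.55
cardiac_output: 10.19
gfr: 0.0786
portal_flow: 2.0
enterocyte_volume: 0.002
renal_clearance_rule: fup_times_gfr
tissues:
- {name: lung,          volume: 0.00175,  blood_flow: 10.19, kp: 7.52}
- {name: adipose,       volume: 0.00200,  blood_flow: 0.30,  kp: 69.58}
- {name: muscle,        volume: 0.1414,   blood_flow: 1.72,  kp: 3.66}
- {name: liver,         volume: 0.01281,  blood_flow: 5.90,  kp: 6.15}
- {name: spleen,        volume: 0.0007,   blood_flow: 0.06,  kp: 3.39}
- {name: heart,         volume: 0.001155, blood_flow: 0.30,  kp: 5.06}
- {name: brain,         volume: 0.001995, blood_flow: 0.12,  kp: 15.89}
- {name: kidney,        volume: 0.002555, blood_flow: 0.85,  kp: 6.00}
- {name: skin,          volume: 0.0665,   blood_flow: 0.35,  kp: 8.44}
- {name: reproductive,  volume: 0.003815, blood_flow: 0.03,  kp: 6.00}
- {name: red_marrow,    volume: 0.005915, blood_flow: 0.17,  kp: 8.09}
- {name: yellow_marrow, volume: 0.000615, blood_flow: 0.05,  kp: 69.59}
- {name: rest,          volume: 0.05,     blood_flow: 0.40,  kp: 3.39}
gi:
- {name: stomach,  volume: 3.4, transit_time: 0.25, ph: 1.7, bile_salt_conc: 0.0, sa_v: 0.0, absorption_enabled: false}
- {name: duodenum, volume: 1.0, transit_time: 0.13, ph: 6.2, bile_salt_conc: 3.0, sa_v: 15.6}
- {name: jejunum1, volume: 1.5, transit_time: 0.30, ph: 6.4, bile_salt_conc: 2.5, sa_v: 15.6}
- {name: jejunum2, volume: 1.5, transit_time: 0.30, ph: 6.6, bile_salt_conc: 2.0, sa_v: 13.0}
- {name: ileum1,   volume: 1.2, transit_time: 0.25, ph: 6.9, bile_salt_conc: 1.5, sa_v: 10.4}
- {name: ileum2,   volume: 1.0, transit_time: 0.25, ph: 7.1, bile_salt_conc: 1.0, sa_v: 7.8}
- {name: ileum3,   volume: 0.8, transit_time: 0.25, ph: 7.3, bile_salt_conc: 0.5, sa_v: 5.2}
- {name: caecum,   volume: 3.0, transit_time: 2.5,  ph: 6.2, bile_salt_conc: 0.0, sa_v: 1.3}
- {name: colon,    volume: 2.0, transit_time: 4.0,  ph: 6.6, bile_salt_conc: 0.0, sa_v: 0.78}
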