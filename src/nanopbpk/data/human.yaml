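# Fasted healthy adult male physiology, reference body weight 67.73 kg.
# Tissue volumes/flows from standard adult tables; adipose/yellow-marrow
# volumes carry a single calibrated scale so the steady-state volume of
# distribution matches the model's reported value (see docs/methods.md).
# Kp column: Rodgers-Rowland values.
# Units: volumes L (GI lumen mL), flows L/h, gfr L/h, transit h, bile mM,
# sa_v 1/cm.
species: human
reference_body_weight: 67.73
venous_volume: 3.35
arterial_volume: 1.68
plasma_fraction: 0.55
cardiac_output: 325.0
gfr: 7.2
portal_flow: 60.0
enterocyte_volume: 0.25
renal_clearance_rule: fup_times_gfr
tissues:
- {name: lung,          volume: 0.53,  blood_flow: 325.0, kp: 0.65}
- {name: adipose,       volume: 18.936, blood_flow: 16.0,  kp: 27.59}
- {name: muscle,        volume: 28.06, blood_flow: 55.0,  kp: 3.09}
- {name: liver,         volume: 1.742, blood_flow: 90.0,  kp: 5.05}
- {name: spleen,        volume: 0.18,  blood_flow: 5.4,   kp: 3.11}
- {name: heart,         volume: 0.31,  blood_flow: 13.0,  kp: 1.97}
- {name: brain,         volume: 1.40,  blood_flow: 39.0,  kp: 8.11}
- {name: kidney,        volume: 0.30,  blood_flow: 62.0,  kp: 3.05}
- {name: skin,          volume: 7.55,  blood_flow: 19.0,  kp: 3.79}
- {name: reproductive,  volume: 0.035, blood_flow: 0.3,   kp: 3.05}
- {name: red_marrow,    volume: 1.12,  blood_flow: 10.0,  kp: 8.86}
- {name: yellow_marrow, volume: 2.29,  blood_flow: 2.7,   kp: 27.59}
- {name: rest,          volume: 3.0,   blood_flow: 18.0,  kp: 3.11}
gi:
- {name: stomach,  volume: 46.0, transit_time: 0.25, ph: 1.3, bile_salt_conc: 0.0, sa_v: 0.0, absorption_enabled: false}
- {name: duodenum, volume: 42.0, transit_time: 0.26, ph: 6.0, bile_salt_conc: 2.8, sa_v: 4.16}
- {name: jejunum1, volume: 80.0, transit_time: 0.93, ph: 6.2, bile_salt_conc: 2.4, sa_v: 4.16}
- {name: jejunum2, volume: 70.0, transit_time: 0.74, ph: 6.4, bile_salt_conc: 2.0, sa_v: 4.0}
- {name: ileum1,   volume: 50.0, transit_time: 0.58, ph: 6.6, bile_salt_conc: 1.5, sa_v: 3.68}
- {name: ileum2,   volume: 40.0, transit_time: 0.42, ph: 6.9, bile_salt_conc: 1.0, sa_v: 3.2}
- {name: ileum3,   volume: 30.0, transit_time: 0.29, ph: 7.4, bile_salt_conc: 0.5, sa_v: 2.72}
- {name: caecum,   volume: 47.0, transit_time: 4.5,  ph: 6.4, bile_salt_conc: 0.0, sa_v: 0.48}
- {name: colon,    volume: 50.0, transit_time: 13.5, ph: 6.8, bile_salt_conc: 0.0, sa_v: 0.32}
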