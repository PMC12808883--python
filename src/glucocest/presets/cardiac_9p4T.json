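{
 "description": "Five-pool cardiac tissue model at baseline (10 mM glucose) with the 9.4 T cardiac glucoCEST saturation scheme: single 140 ms block pulse at 2 uT per 398 ms TR, 15 deg FLASH readout, 21 interleaved offsets over +/-2000 Hz in 200 Hz steps, S0 references at +/-15 ppm.",
 "tissue": {
  "water": {"name": "water", "fraction": 1.0, "t1_s": 1.429, "t2_s": 0.029, "exchange_rate_hz": 0.0, "chemical_shift_ppm": 0.0, "lineshape": "lorentzian"},
  "solutes": [
   {"name": "mt", "fraction": 0.01, "t1_s": 1.0, "t2_s": 4.0e-05, "exchange_rate_hz": 30.0, "chemical_shift_ppm": -3.0, "lineshape": "lorentzian"},
   {"name": "hydroxyl", "fraction": 0.00045045045045045046, "t1_s": 1.0, "t2_s": 0.1, "exchange_rate_hz": 3500.0, "chemical_shift_ppm": 1.5, "lineshape": "lorentzian"},
   {"name": "amine", "fraction": 9e-05, "t1_s": 1.0, "t2_s": 0.1, "exchange_rate_hz": 5000.0, "chemical_shift_ppm": 3.0, "lineshape": "lorentzian"},
   {"name": "amide", "fraction": 0.000135, "t1_s": 1.0, "t2_s": 0.1, "exchange_rate_hz": 50.0, "chemical_shift_ppm": 3.5, "lineshape": "lorentzian"}
  ]
 },
 "sequence": {
  "b1_uT": 2.0,
  "tsat_ms": 140.0,
  "tr_ms": 398.0,
  "flip_angle_deg": 15.0,
  "offsets_hz": [-2000, 2000, -1800, 1800, -1600, 1600, -1400, 1400, -1200, 1200, -1000, 1000, -800, 800, -600, 600, -400, 400, -200, 200, 0],
  "s0_offsets_ppm": [15.0, -15.0],
  "ref_freq_mhz": 400.2,
  "saturation_mode": "cumulative",
  "max_blocks": 200,
  "convergence_tol": 1e-06
 }
}
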