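{
 "material": {
  "rho": 1200.0,
  "Cp": 1500.0,
  "k_cond": 0.2,
  "eta_pl": 0.9,
  "mu_fric": 0.14126089914187545,
  "K_rad": 0.4,
  "h_wall": 300.0,
  "h_punch": 4707.85893544916,
  "T_tool": 25.0
 },
 "tolerance": {
  "T_crit": 41.89163380658298,
  "z_T": 12.128349622716348,
  "s_max": 1.0
 },
 "RD_0": 0.45,
 "RD_max": 0.95,
 "P_c": 130.0,
 "radius": 0.003,
 "mass": 0.00013,
 "rho_true": 1500.0,
 "gap_s": 0.2,
 "unload_frac": 0.05,
 "speed_floor": 1.0,
 "n_shells": 50,
 "n_ramp": 300,
 "n_unload": 80,
 "n_gap": 80,
 "kinetics": "peak",
 "D_crit_s": 1.0
}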