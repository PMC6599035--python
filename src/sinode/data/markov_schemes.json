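{
 "_comment": "Single-channel scheme parameters. Gate convention: y_inf = 1/(1+exp((V-vh)/k)), tau = base + amp/(exp((V-vc)/k1)+exp(-(V-vc)/k2)) in ms. HCN4's unitary conductance of 1.0 pS is the analysis anchor; all other g_u values are placeholder estimates, not measured quantities.",
 "hcn4": {
  "topology": "two_state",
  "g_u_pS": 1.0,
  "E_rev_mV": -30.0,
  "activation": {
   "y_inf": {"vh": -90.0, "k": 8.0},
   "tau": {"base": 100.0, "amp": 1200.0, "vc": -90.0, "k1": 15.0, "k2": 15.0}
  }
 },
 "hcn1": {
  "topology": "two_state",
  "g_u_pS": 1.0,
  "_g_u_note": "placeholder",
  "E_rev_mV": -30.0,
  "activation": {
   "y_inf": {"vh": -80.0, "k": 7.5},
   "tau": {"base": 20.0, "amp": 300.0, "vc": -80.0, "k1": 12.0, "k2": 12.0}
  }
 },
 "cav12": {
  "topology": "four_state",
  "g_u_pS": 2.5,
  "_g_u_note": "placeholder",
  "E_rev_mV": 45.0,
  "activation": {
   "y_inf": {"vh": -15.0, "k": -5.0},
   "tau": {"base": 1.0, "amp": 2.0, "vc": -15.0, "k1": 12.0, "k2": 12.0}
  },
  "inactivation": {
   "y_inf": {"vh": -35.0, "k": 4.0},
   "tau": {"base": 15.0, "amp": 50.0, "vc": -35.0, "k1": 10.0, "k2": 10.0}
  },
  "slow_inactivation": {
   "y_inf": {"vh": -40.0, "k": 4.0},
   "tau": {"base": 150.0, "amp": 300.0, "vc": -40.0, "k1": 12.0, "k2": 12.0}
  }
 },
 "cav32": {
  "topology": "four_state",
  "g_u_pS": 1.7,
  "_g_u_note": "placeholder",
  "E_rev_mV": 45.0,
  "activation": {
   "y_inf": {"vh": -50.0, "k": -5.0},
   "tau": {"base": 1.5, "amp": 3.0, "vc": -50.0, "k1": 10.0, "k2": 10.0}
  },
  "inactivation": {
   "y_inf": {"vh": -70.0, "k": 4.0},
   "tau": {"base": 10.0, "amp": 30.0, "vc": -70.0, "k1": 10.0, "k2": 10.0}
  },
  "slow_inactivation": {
   "y_inf": {"vh": -75.0, "k": 4.0},
   "tau": {"base": 100.0, "amp": 200.0, "vc": -75.0, "k1": 12.0, "k2": 12.0}
  }
 },
 "erg": {
  "topology": "four_state",
  "g_u_pS": 2.0,
  "_g_u_note": "placeholder",
  "E_rev_mV": -85.0,
  "activation": {
   "y_inf": {"vh": -20.0, "k": -7.0},
   "tau": {"base": 20.0, "amp": 200.0, "vc": -20.0, "k1": 14.0, "k2": 14.0}
  },
  "inactivation": {
   "y_inf": {"vh": -60.0, "k": 5.0},
   "tau": {"base": 2.0, "amp": 5.0, "vc": -60.0, "k1": 10.0, "k2": 10.0}
  },
  "slow_inactivation": {
   "y_inf": {"vh": -55.0, "k": 5.0},
   "tau": {"base": 50.0, "amp": 100.0, "vc": -55.0, "k1": 12.0, "k2": 12.0}
  }
 }
}
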