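{
 "name": "sn_minimal",
 "C_m": 25.0,
 "currents": {
  "I_Na": {
   "name": "I_Na",
   "g_max": 100.0,
   "E_rev": 60.0,
   "gates": [
    {
     "name": "m",
     "exponent": 3.0,
     "vh": -38.0,
     "k": -6.0,
     "tau": {
      "base": 0.03,
      "amp": 0.25,
      "vc": -45.0,
      "k1": 10.0,
      "k2": 10.0
     },
     "v_half_shift": 0.0
    },
    {
     "name": "h",
     "exponent": 1.0,
     "vh": -72.0,
     "k": 6.0,
     "tau": {
      "base": 0.4,
      "amp": 30.0,
      "vc": -75.0,
      "k1": 8.0,
      "k2": 8.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_CaL": {
   "name": "I_CaL",
   "g_max": 8.0,
   "E_rev": 60.0,
   "gates": [
    {
     "name": "d",
     "exponent": 1.0,
     "vh": -25.0,
     "k": -6.0,
     "tau": {
      "base": 0.8,
      "amp": 1.5,
      "vc": -12.0,
      "k1": 12.0,
      "k2": 12.0
     },
     "v_half_shift": 0.0
    },
    {
     "name": "f",
     "exponent": 1.0,
     "vh": -30.0,
     "k": 5.0,
     "tau": {
      "base": 12.0,
      "amp": 60.0,
      "vc": -30.0,
      "k1": 10.0,
      "k2": 10.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_to": {
   "name": "I_to",
   "g_max": 0.8,
   "E_rev": -85.0,
   "gates": [
    {
     "name": "r",
     "exponent": 1.0,
     "vh": -5.0,
     "k": -9.0,
     "tau": {
      "base": 1.5,
      "amp": 3.0,
      "vc": -5.0,
      "k1": 12.0,
      "k2": 12.0
     },
     "v_half_shift": 0.0
    },
    {
     "name": "s",
     "exponent": 1.0,
     "vh": -38.0,
     "k": 5.0,
     "tau": {
      "base": 25.0,
      "amp": 80.0,
      "vc": -38.0,
      "k1": 10.0,
      "k2": 10.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_Kur": {
   "name": "I_Kur",
   "g_max": 0.0,
   "E_rev": -85.0,
   "gates": [
    {
     "name": "a",
     "exponent": 1.0,
     "vh": -8.0,
     "k": -8.0,
     "tau": {
      "base": 2.0,
      "amp": 5.0,
      "vc": -8.0,
      "k1": 12.0,
      "k2": 12.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_Kr": {
   "name": "I_Kr",
   "g_max": 5.2,
   "E_rev": -85.0,
   "gates": [
    {
     "name": "xr",
     "exponent": 1.0,
     "vh": -22.0,
     "k": -7.0,
     "tau": {
      "base": 30.0,
      "amp": 250.0,
      "vc": -22.0,
      "k1": 14.0,
      "k2": 14.0
     },
     "v_half_shift": 0.0
    },
    {
     "name": "rect",
     "exponent": 1.0,
     "vh": 20.0,
     "k": 14.0,
     "tau": null,
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_K1": {
   "name": "I_K1",
   "g_max": 2.2,
   "E_rev": -85.0,
   "gates": [
    {
     "name": "kin",
     "exponent": 1.0,
     "vh": -60.0,
     "k": 6.0,
     "tau": null,
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_b": {
   "name": "I_b",
   "g_max": 0.23,
   "E_rev": -20.0,
   "gates": [],
   "kind": "ohmic"
  },
  "I_f_HCN4": {
   "name": "I_f_HCN4",
   "g_max": 6.255,
   "E_rev": -30.0,
   "gates": [
    {
     "name": "y",
     "exponent": 1.0,
     "vh": -80.0,
     "k": 9.0,
     "tau": {
      "base": 40.0,
      "amp": 400.0,
      "vc": -80.0,
      "k1": 14.0,
      "k2": 14.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_f_HCN1": {
   "name": "I_f_HCN1",
   "g_max": 0.45,
   "E_rev": -30.0,
   "gates": [
    {
     "name": "y",
     "exponent": 1.0,
     "vh": -75.0,
     "k": 8.0,
     "tau": {
      "base": 20.0,
      "amp": 200.0,
      "vc": -75.0,
      "k1": 12.0,
      "k2": 12.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  },
  "I_CaT": {
   "name": "I_CaT",
   "g_max": 3.0,
   "E_rev": 45.0,
   "gates": [
    {
     "name": "dT",
     "exponent": 1.0,
     "vh": -50.0,
     "k": -5.0,
     "tau": {
      "base": 1.2,
      "amp": 2.0,
      "vc": -50.0,
      "k1": 10.0,
      "k2": 10.0
     },
     "v_half_shift": -7.0
    },
    {
     "name": "fT",
     "exponent": 1.0,
     "vh": -65.0,
     "k": 5.0,
     "tau": {
      "base": 8.0,
      "amp": 25.0,
      "vc": -68.0,
      "k1": 10.0,
      "k2": 10.0
     },
     "v_half_shift": 0.0
    }
   ],
   "kind": "ohmic"
  }
 },
 "calcium": {
  "v_up": 0.36000000000000004,
  "k_rel": 0.002,
  "K_up": 0.25,
  "K_rel": 0.6,
  "influx_scale": 0.01,
  "sr_volume_ratio": 15.0,
  "ca_current_names": [
   "I_CaL",
   "I_CaT"
  ],
  "cai0": 0.1,
  "casr0": 100.0
 },
 "initial_V": -65.0,
 "version": "synthetic-1: sinus-node-like parameterization obtained by applying the shipped proteomic conversion table to the synthetic atrial model; the discrete HCN4 funny-current conductance (6.255 nS) is the copy-number anchor"
}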