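{
 "name": "atrial_minimal",
 "version": "synthetic-1: minimal mouse-atrial-like parameterization authored for this package; not a transcription of any published model",
 "C_m": 50.0,
 "initial_V": -78.0,
 "currents": {
  "I_Na": {
   "name": "I_Na",
   "g_max": 250.0,
   "E_rev": 60.0,
   "kind": "ohmic",
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
     }
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
     }
    }
   ]
  },
  "I_CaL": {
   "name": "I_CaL",
   "g_max": 10.0,
   "E_rev": 60.0,
   "kind": "ohmic",
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
     }
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
     }
    }
   ]
  },
  "I_to": {
   "name": "I_to",
   "g_max": 8.0,
   "E_rev": -85.0,
   "kind": "ohmic",
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
     }
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
     }
    }
   ]
  },
  "I_Kur": {
   "name": "I_Kur",
   "g_max": 5.0,
   "E_rev": -85.0,
   "kind": "ohmic",
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
     }
    }
   ]
  },
  "I_Kr": {
   "name": "I_Kr",
   "g_max": 4.0,
   "E_rev": -85.0,
   "kind": "ohmic",
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
     }
    },
    {
     "name": "rect",
     "exponent": 1.0,
     "vh": 20.0,
     "k": 14.0,
     "tau": null
    }
   ]
  },
  "I_K1": {
   "name": "I_K1",
   "g_max": 2.2,
   "E_rev": -85.0,
   "kind": "ohmic",
   "gates": [
    {
     "name": "kin",
     "exponent": 1.0,
     "vh": -60.0,
     "k": 6.0,
     "tau": null
    }
   ]
  },
  "I_b": {
   "name": "I_b",
   "g_max": 0.23,
   "E_rev": -20.0,
   "kind": "ohmic",
   "gates": []
  }
 },
 "calcium": {
  "v_up": 0.4,
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
 }
}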