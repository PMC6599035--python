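{
 "_comment": "Atrial -> sinus-node conversion table. Ratios are synthetic stand-ins consistent with the qualitative proteomic picture (HCN and Cav3 strongly node-enriched, Nav1.5 lower in the node, Ca-clock proteins essentially unchanged); the I_Kur/I_to fractions, the Cm change and the I_CaT -7 mV shift are fixed conventions of the conversion procedure.",
 "actions": [
  {
   "target": "C_m",
   "action": "set_cm",
   "value": 25.0
  },
  {
   "target": "I_Na",
   "action": "scale",
   "value": 0.4
  },
  {
   "target": "I_CaL",
   "action": "scale",
   "value": 0.8
  },
  {
   "target": "I_Kr",
   "action": "scale",
   "value": 1.3
  },
  {
   "target": "I_f_HCN4",
   "action": "insert",
   "payload": {
    "name": "I_f_HCN4",
    "g_max": 6.255,
    "E_rev": -30.0,
    "kind": "ohmic",
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
      }
     }
    ]
   }
  },
  {
   "target": "I_f_HCN1",
   "action": "insert",
   "payload": {
    "name": "I_f_HCN1",
    "g_max": 0.45,
    "E_rev": -30.0,
    "kind": "ohmic",
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
      }
     }
    ]
   }
  },
  {
   "target": "I_CaT",
   "action": "insert",
   "payload": {
    "name": "I_CaT",
    "g_max": 3.0,
    "E_rev": 45.0,
    "kind": "ohmic",
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
      }
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
      }
     }
    ]
   }
  },
  {
   "target": "I_CaT",
   "action": "shift_vhalf",
   "value": -7.0,
   "gate": "dT"
  },
  {
   "target": "I_Kur",
   "action": "set_fraction",
   "value": 0.0
  },
  {
   "target": "I_to",
   "action": "set_fraction",
   "value": 0.1
  },
  {
   "target": "J_up",
   "action": "scale_calcium",
   "value": 0.9
  },
  {
   "target": "J_rel",
   "action": "scale_calcium",
   "value": 1.0
  }
 ]
}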