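{
 "couplings": [
  {
   "J_cm1": -21.2,
   "i": 1,
   "j": 2
  },
  {
   "J_cm1": 10.8,
   "i": 1,
   "j": 3
  },
  {
   "J_cm1": 13.5,
   "i": 1,
   "j": 4
  },
  {
   "J_cm1": 28.2,
   "i": 2,
   "j": 3
  },
  {
   "J_cm1": 0.8,
   "i": 2,
   "j": 4
  },
  {
   "J_cm1": -45.0,
   "i": 3,
   "j": 4
  }
 ],
 "metadata": {
  "printed_S_ES": "3/2",
  "printed_S_GS": "1/2",
  "printed_dE_ES_cm1": 37.2,
  "printed_dE_doublet_cm1": null,
  "source_table": "exchange-coupling table",
  "valence_distribution": "III,IV,IV,IV",
  "valence_source": "prose"
 },
 "name": "A8",
 "sites": [
  {
   "index": 1,
   "label": "Mn1",
   "local_spin": "2",
   "oxidation_state": "III"
  },
  {
   "index": 2,
   "label": "Mn2",
   "local_spin": "3/2",
   "oxidation_state": "IV"
  },
  {
   "index": 3,
   "label": "Mn3",
   "local_spin": "3/2",
   "oxidation_state": "IV"
  },
  {
   "index": 4,
   "label": "Mn4",
   "local_spin": "3/2",
   "oxidation_state": "IV"
  }
 ]
}
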