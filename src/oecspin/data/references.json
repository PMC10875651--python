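[
 {
  "ammonia_treated": true,
  "hfc_ratios": [
   1.52,
   1.04,
   1.29
  ],
  "his332_aiso": 7.2,
  "his332_eta": 0.8,
  "mn_hfcs": [
   313,
   206,
   198,
   153
  ],
  "n14_aiso": 2.3,
  "n14_eta": 0.4,
  "organism": "Synechocystis"
 },
 {
  "ammonia_treated": true,
  "hfc_ratios": [
   1.55,
   1.06,
   1.21
  ],
  "mn_hfcs": [
   318,
   205,
   193,
   160
  ],
  "n14_aiso": 2.3,
  "n14_eta": 0.6,
  "organism": "Spinach"
 },
 {
  "ammonia_treated": true,
  "ea_difference": 2.7,
  "hfc_ratios": [
   1.43,
   1.03,
   1.21
  ],
  "his332_aiso": 7.2,
  "his332_eta": 0.8,
  "mn_hfcs": [
   331,
   231,
   225,
   186
  ],
  "n14_aiso": 2.4,
  "n14_eta": 0.5,
  "o17_aiso": {
   "exchangeable": 7.0,
   "terminal": 3.1
  },
  "organism": "T. vestitus"
 },
 {
  "ammonia_treated": false,
  "hfc_ratios": [
   1.47,
   1.02,
   1.07
  ],
  "his332_aiso": 7.2,
  "his332_eta": 0.8,
  "mn_hfcs": [
   307,
   209,
   204,
   190
  ],
  "organism": "Synechocystis (untreated S2)"
 },
 {
  "ammonia_treated": false,
  "hfc_ratios": [
   1.28,
   1.18,
   1.06
  ],
  "mn_hfcs": [
   310,
   242,
   205,
   194
  ],
  "organism": "Spinach (untreated S2)"
 },
 {
  "ammonia_treated": false,
  "hfc_ratios": [
   1.45,
   1.01,
   1.17
  ],
  "his332_aiso": 7.1,
  "his332_eta": 0.8,
  "mn_hfcs": [
   333,
   230,
   227,
   194
  ],
  "o17_aiso": {
   "O5": 9.7,
   "W1": 4.5,
   "W2": 1.4
  },
  "organism": "T. vestitus (untreated S2)"
 }
]
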