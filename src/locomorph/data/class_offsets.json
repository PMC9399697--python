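{
 "measurements": [
  "ATL",
  "ATW",
  "ABW",
  "ATrW",
  "LTL",
  "MTL",
  "MBH",
  "LBH",
  "EL",
  "EW",
  "SL",
  "SW",
  "HL",
  "HW",
  "CFW"
 ],
 "offsets": {
  "arboreal": [
   0.726667,
   -0.073333,
   -0.673333,
   -0.073333,
   -0.073333,
   -0.073333,
   0.226667,
   -0.073333,
   -0.073333,
   -0.073333,
   -0.073333,
   -0.073333,
   -0.073333,
   0.526667,
   -0.073333
  ],
  "cursorial": [
   -0.066667,
   -0.666667,
   -0.066667,
   -0.066667,
   0.733333,
   0.733333,
   -0.066667,
   -0.366667,
   -0.066667,
   -0.066667,
   -0.066667,
   -0.066667,
   0.233333,
   -0.066667,
   -0.066667
  ],
  "fossorial": [
   -0.046667,
   -0.046667,
   0.553333,
   -0.046667,
   -0.446667,
   -0.046667,
   -0.046667,
   -0.046667,
   -0.046667,
   0.253333,
   -0.046667,
   0.553333,
   -0.446667,
   -0.046667,
   -0.046667
  ],
  "gliding": [
   0.893333,
   0.493333,
   -0.906667,
   -0.106667,
   -0.106667,
   -0.106667,
   0.293333,
   -0.106667,
   -0.106667,
   -0.106667,
   -0.106667,
   -0.106667,
   0.293333,
   -0.106667,
   -0.106667
  ],
  "ricochetal": [
   -0.033333,
   -0.433333,
   -0.033333,
   -0.033333,
   0.966667,
   -0.033333,
   -0.033333,
   0.566667,
   -0.033333,
   -0.333333,
   -0.033333,
   -0.433333,
   -0.033333,
   -0.033333,
   -0.033333
  ],
  "semi-aquatic": [
   -0.106667,
   0.693333,
   0.893333,
   -0.106667,
   -1.106667,
   -0.606667,
   -0.106667,
   -0.106667,
   0.693333,
   -0.106667,
   -0.106667,
   -0.106667,
   -0.106667,
   -0.106667,
   0.393333
  ],
  "semi-fossorial": [
   -0.02,
   -0.02,
   0.28,
   -0.02,
   -0.22,
   -0.02,
   -0.02,
   -0.02,
   -0.02,
   -0.02,
   -0.02,
   0.38,
   -0.22,
   -0.02,
   -0.02
  ],
  "terrestrial": [
   0.093333,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667,
   -0.006667
  ]
 }
}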