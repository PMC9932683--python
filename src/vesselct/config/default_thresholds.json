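{
  "_comment": "UNCALIBRATED defaults derived from the synthetic phantom layer means (ethanol 500 HU, intima 2000, media 4000-5000 incl. collagen contrast, adventitia 6500). Interval boundaries sit at midpoints between adjacent layer levels. Calibrate against your own stain concentration and scanner before use on real data.",
  "intervals": {
    "lumen": [-500.0, 1250.0],
    "intima": [1250.0, 3000.0],
    "media": [3000.0, 5750.0],
    "adventitia": [5750.0, 7250.0]
  }
}
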