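{
  "fisher_2d": {
    "feature_names": ["EY", "OG"],
    "weights": [15.01, -43.55],
    "bias": 1.454,
    "positive_label": "EC"
  },
  "fisher_3d": {
    "feature_names": ["EY", "LG", "OG"],
    "weights": [41.52, -55.34, -46.79],
    "bias": 3.263,
    "positive_label": "EC"
  },
  "srgb": {
    "feature_names": ["R", "G", "B"],
    "weights": [83.41, -368.9, 365.8],
    "bias": -74.22,
    "positive_label": "EC"
  }
}
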