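{
  "intercept": 0.08,
  "terms": [
    {
      "coef": -0.009,
      "factors": [
        {"variable": "AvgTmaxLag1", "knot": 32.95, "direction": "downward"}
      ]
    },
    {
      "coef": 0.179,
      "factors": [
        {"variable": "AvgTmaxLag1", "knot": 32.95, "direction": "upward"}
      ]
    },
    {
      "coef": 0.019,
      "factors": [
        {"variable": "Nindex1", "knot": 79.65, "direction": "upward"}
      ]
    }
  ],
  "meta": {
    "n_obs": null,
    "gcv": null,
    "rss": null,
    "note": "Published additive hinge model for all-visitor standardized heat-illness morbidity (HWwhole)."
  }
}
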