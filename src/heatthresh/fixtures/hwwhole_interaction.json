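{
  "intercept": 0.028,
  "terms": [
    {
      "coef": 0.051,
      "factors": [
        {"variable": "Tavg", "knot": 25.1, "direction": "upward"}
      ]
    },
    {
      "coef": 1.157,
      "factors": [
        {"variable": "AvgTmaxLag1", "knot": 32.95, "direction": "upward"}
      ]
    },
    {
      "coef": 0.010,
      "factors": [
        {"variable": "Tavg", "knot": 25.1, "direction": "upward"},
        {"variable": "Whum", "knot": 81.3, "direction": "upward"}
      ]
    },
    {
      "coef": 0.030,
      "factors": [
        {"variable": "AvgTmaxLag1", "knot": 32.85, "direction": "upward"},
        {"variable": "Whum", "knot": -23.8, "direction": "downward"}
      ]
    }
  ],
  "meta": {
    "n_obs": null,
    "gcv": null,
    "rss": null,
    "note": "Published second-order interaction model for HWwhole. The last factor is encoded verbatim from the source, max(0, 57.5 - Whum - 81.3) = max(-23.8 - Whum, 0): a downward hinge at knot -23.8 that is identically zero for physical humidity."
  }
}
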