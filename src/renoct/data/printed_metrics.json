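{
  "_comment": "Published per-class performance values (percent, 2 decimals) that must be derivable from the bundled confusion-matrix tables.",
  "table1a": {
    "metrics": {
      "tumor": {"accuracy": 98.19, "precision": 91.85, "recall": 99.83, "f1": 95.67},
      "calyx": {"accuracy": 78.77, "precision": 43.18, "recall": 19.47, "f1": 26.84}
    }
  },
  "table2a": {
    "accuracy": {
      "tumor": 99.51,
      "cortex": 98.96,
      "medulla": 99.78,
      "calyx": 99.09,
      "fat": 99.27,
      "pelvis": 99.95
    },
    "misclassification_percent": {"calyx->tumor": 1.48}
  },
  "table2b": {
    "accuracy": {
      "tumor": 99.48,
      "cortex": 99.58,
      "medulla": 99.88,
      "calyx": 99.27,
      "fat": 99.65,
      "pelvis": 99.95
    }
  }
}
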