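{
  "variables": [
    {
      "name": "N",
      "role": "input",
      "domain": [0, 100],
      "levels": [
        {"label": "LOW", "lo": -1, "hi": 20},
        {"label": "ADEQUATE", "lo": 20.1, "hi": 41},
        {"label": "HIGH", "lo": 41.1, "hi": 70},
        {"label": "EXCESSIVE", "lo": 70.1, "hi": 100}
      ]
    },
    {
      "name": "P",
      "role": "input",
      "domain": [0, 150],
      "levels": [
        {"label": "LOW", "lo": -1, "hi": 20},
        {"label": "ADEQUATE", "lo": 20.1, "hi": 40},
        {"label": "HIGH", "lo": 40.1, "hi": 100},
        {"label": "EXCESSIVE", "lo": 100.1, "hi": 150}
      ]
    },
    {
      "name": "K",
      "role": "input",
      "domain": [0, 1500],
      "levels": [
        {"label": "LOW", "lo": 0, "hi": 150},
        {"label": "ADEQUATE", "lo": 150.1, "hi": 250},
        {"label": "HIGH", "lo": 250.1, "hi": 800},
        {"label": "EXCESSIVE", "lo": 800.1, "hi": 1500}
      ]
    },
    {
      "name": "R.N",
      "role": "output",
      "domain": [0, 100],
      "levels": [
        {"label": "LOW", "lo": 0, "hi": 30},
        {"label": "AVERAGE", "lo": 30, "hi": 70},
        {"label": "HIGH", "lo": 70, "hi": 100}
      ]
    },
    {
      "name": "R.P",
      "role": "output",
      "domain": [0, 100],
      "levels": [
        {"label": "LOW", "lo": 0, "hi": 30},
        {"label": "AVERAGE", "lo": 30, "hi": 70},
        {"label": "HIGH", "lo": 70, "hi": 100}
      ]
    },
    {
      "name": "R.K",
      "role": "output",
      "domain": [0, 100],
      "levels": [
        {"label": "LOW", "lo": 0, "hi": 20},
        {"label": "AVERAGE", "lo": 20, "hi": 70},
        {"label": "HIGH", "lo": 70, "hi": 100}
      ]
    },
    {
      "name": "S.F",
      "role": "output",
      "domain": [0, 100],
      "levels": [
        {"label": "LOW", "lo": 0, "hi": 40},
        {"label": "AVERAGE", "lo": 40, "hi": 80},
        {"label": "HIGH", "lo": 80, "hi": 100}
      ]
    }
  ]
}
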