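{
  "comment": "Decay data for the 225Ac alpha cascade, from evaluated nuclear data (ENSDF/NuDat). Half-lives in seconds; gamma intensities are absolute, per decay of the emitting nuclide.",
  "version": "2024-1",
  "nuclides": [
    {
      "name": "Ac-225",
      "half_life_s": 857088.0,
      "modes": [
        {"mode": "alpha", "fraction": 1.0, "daughter": "Fr-221"}
      ],
      "gammas": [
        {"keV": 99.8, "intensity": 0.0101}
      ]
    },
    {
      "name": "Fr-221",
      "half_life_s": 288.0,
      "modes": [
        {"mode": "alpha", "fraction": 1.0, "daughter": "At-217"}
      ],
      "gammas": [
        {"keV": 218.12, "intensity": 0.1144}
      ]
    },
    {
      "name": "At-217",
      "half_life_s": 0.0323,
      "modes": [
        {"mode": "alpha", "fraction": 1.0, "daughter": "Bi-213"}
      ],
      "gammas": []
    },
    {
      "name": "Bi-213",
      "half_life_s": 2736.6,
      "modes": [
        {"mode": "beta-", "fraction": 0.978, "daughter": "Po-213"},
        {"mode": "alpha", "fraction": 0.022, "daughter": "Tl-209"}
      ],
      "gammas": [
        {"keV": 440.45, "intensity": 0.261}
      ]
    },
    {
      "name": "Po-213",
      "half_life_s": 3.72e-06,
      "modes": [
        {"mode": "alpha", "fraction": 1.0, "daughter": "Pb-209"}
      ],
      "gammas": []
    },
    {
      "name": "Tl-209",
      "half_life_s": 129.72,
      "modes": [
        {"mode": "beta-", "fraction": 1.0, "daughter": "Pb-209"}
      ],
      "gammas": [
        {"keV": 465.13, "intensity": 0.969},
        {"keV": 1567.09, "intensity": 0.997}
      ]
    },
    {
      "name": "Pb-209",
      "half_life_s": 11642.4,
      "modes": [
        {"mode": "beta-", "fraction": 1.0, "daughter": "Bi-209"}
      ],
      "gammas": []
    },
    {
      "name": "Bi-209",
      "half_life_s": null,
      "modes": [],
      "gammas": []
    }
  ]
}
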