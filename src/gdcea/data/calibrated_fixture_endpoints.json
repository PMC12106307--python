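{
  "achieved": {
    "cost_mono": 529928.5600000002,
    "qalys_mono": 1.4799999999999889,
    "cost_combo": 650629.5599999998,
    "qalys_combo": 2.0200000000000173
  },
  "max_rel_error": 8.659739592076221e-15,
  "converged": true,
  "n_evaluations": 5701,
  "hazards": {
    "mono": [
      0.013906273386670033,
      0.03024896450812932,
      0.37969870616326257
    ],
    "combo": [
      1.5005316811776755e-05,
      0.037366234803034394,
      0.0877296435324357
    ]
  },
  "cost_multipliers": {
    "mono": 0.7002840776231465,
    "combo": 0.5764061604096037
  },
  "selection": {
    "tornado_top": "imiglucerase_pack_price",
    "ceac_prob": 0.9366666666666666,
    "score": 0.0006666666666665932
  },
  "targets": {
    "cost_mono": 529928.56,
    "qalys_mono": 1.48,
    "cost_combo": 650629.56,
    "qalys_combo": 2.02,
    "tolerance": 0.001
  },
  "note": "Synthetic regression fixture: hazards calibrated so the model reproduces the published per-arm totals; NOT the source study's transition estimates. The published cost and QALY totals are mutually inconsistent under full lifelong drug-cost accrual (mono cost implies ~14.9 discounted alive-months, mono QALYs imply >=20.6 at max utility 0.86), so per-arm drug-cost accrual multipliers were fitted alongside the hazards. Among endpoint-matching solutions, the committed pair was selected for consistency with the published tornado ordering and CEAC."
}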