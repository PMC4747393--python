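{
  "description": "Per-subject counts of risk-variants outside the MMR genes among the 35 NGS-analyzed carriers, cross-tabulated against clinical phenotype (rows: exact burden 0..5).",
  "burden_levels": [0, 1, 2, 3, 4, 5],
  "neutral": [5, 6, 1, 1, 0, 0],
  "poor": [2, 4, 5, 8, 2, 1]
}
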