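# Reference mixture of normal components for estimated log2ratio levels.
# One component per copy-number group; means are the idealized log2(CN/2)
# positions for a high-tumor-content sample (cn34 sits between CN=3 and CN=4,
# amp covers CN > 4).  Used when no dataset-level fit is available and as the
# level dictionary of the synthetic-data generators.
fitted_on: reference-defaults
components:
  - {label: cn0, weight: 0.02, mean: -2.0, sd: 0.15}
  - {label: cn1, weight: 0.18, mean: -1.0, sd: 0.15}
  - {label: cn2, weight: 0.60, mean: 0.0, sd: 0.15}
  - {label: cn34, weight: 0.15, mean: 0.8, sd: 0.15}
  - {label: amp, weight: 0.05, mean: 1.6, sd: 0.20}
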