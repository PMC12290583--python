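{
  "comment": "Empirical spatial-uncertainty model for the sample-size-dependent ALE kernel: Euclidean displacement (mm) attributable to template differences (between-lab) and to between-subject variability (shrinks with sqrt(n)). Vendored data, overridable via kernel config.",
  "template_uncertainty_eud_mm": 5.7,
  "subject_uncertainty_eud_mm": 11.6
}
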