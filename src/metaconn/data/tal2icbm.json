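{
  "comment": "Lancaster pooled MNI(ICBM-152)->Talairach affine (icbm2tal). The Talairach->MNI transform used by this package is its matrix inverse, computed at load time. Constants are vendored data, not contract; any 4x4 may be supplied instead.",
  "icbm2tal_pooled": [
    [0.9357, 0.0029, -0.0072, -1.0423],
    [-0.0065, 0.9396, -0.0726, -1.394],
    [0.0103, 0.0752, 0.8967, 3.6475],
    [0.0, 0.0, 0.0, 1.0]
  ]
}
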