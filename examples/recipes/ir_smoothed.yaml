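# IR blood-sample recipe with smoothing before baseline correction.
- kind: cut_region
  lo: 900
  hi: 1800
- kind: savgol
  window: 7
  polyorder: 2
- kind: awls
- kind: peak_norm
  peak: 1650
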