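# Raman / SERS plasma recipe: wider smoothing window, vector normalization.
- kind: savgol
  window: 15
  polyorder: 2
- kind: awls
- kind: vector_norm
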