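# IR tissue recipe: biofingerprint region, rubberband baseline,
# amide I normalization.
- kind: cut_region
  lo: 900
  hi: 1800
- kind: rubberband
- kind: peak_norm
  peak: 1650
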