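exchanges:
  EX_glc:
  - -10.0
  - 1000.0
name: toy_glucose
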