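# Production delta-Ct cutoffs and reference-gene gates for the four-analyte
# RT-qPCR breast-cancer panel (targets normalised against CYFIP1).
dct_cutoffs:
  ESR1: -1.0
  ERBB2: -1.0
  PGR: -3.5
  MKI67: -4.0
cyfip1_valid_max: 35.0
cyfip1_input_max: 31.0
input_gated_analytes: [PGR, MKI67]
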