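{
  "comment": "Zero-field Moessbauer classification ranges for ferric hemes (mm/s). five_coord_HS and six_coord_HS follow the literature ranges for high-spin Fe(III) porphyrins; QS_candidate flags HS-like isomer shifts with anomalously large quadrupole splitting suggestive of a quantum-admixed S=3/2,5/2 state.",
  "ranges": {
    "five_coord_HS": {"delta": [0.25, 0.43], "delta_EQ": [0.4, 1.0]},
    "six_coord_HS": {"delta": [0.32, 0.45], "delta_EQ": [1.22, 2.07]},
    "QS_candidate": {"delta": [0.25, 0.45], "delta_EQ": [2.5, 10.0]}
  }
}
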