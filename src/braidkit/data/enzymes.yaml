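# Type IIS enzyme geometry (standard catalog values). All three leave 4-nt
# 5' overhangs and cut outside their recognition sequence.
BsaI: {recognition: GGTCTC, spacer_len: 1, overhang_len: 4}
BsmBI: {recognition: CGTCTC, spacer_len: 1, overhang_len: 4}
BbsI: {recognition: GAAGAC, spacer_len: 2, overhang_len: 4}
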