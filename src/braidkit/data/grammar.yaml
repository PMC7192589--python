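# Default braidkit grammar: 4-bp fusion-site codes. Edit freely, but keep the
# set pairwise distinct, palindrome-free, and free of reverse-complement
# collisions or ligation fidelity is lost.
junctions:
  unit5: GGAG
  prom3: AATG
  ntag3: CCAT
  cds3x: TTCG
  cds3: GCTT
  unit3: CGCT
  U0: GTCA
  U1: ACTG
  U2: CTGA
  U3: TCCA
  U4: CGGT
  UEND: GCAA
  OMID: TGGC
  E5: CTCG
  E3: CTCA
categories:
  promoter: [unit5, prom3]
  N-tag: [prom3, ntag3]
  CDS: [prom3, cds3]
  C-tag: [cds3x, cds3]
  linker: [ntag3, cds3x]
  terminator: [cds3, unit3]
  barcode: [cds3x, cds3]
  sgRNA: [prom3, cds3]
  other: [prom3, cds3]
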