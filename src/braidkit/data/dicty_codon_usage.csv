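codon,amino_acid,fraction
GCT,A,0.44
GCA,A,0.38
GCC,A,0.12
GCG,A,0.06
AGA,R,0.65
AGG,R,0.13
CGT,R,0.12
CGA,R,0.05
CGC,R,0.03
CGG,R,0.02
AAT,N,0.78
AAC,N,0.22
GAT,D,0.82
GAC,D,0.18
TGT,C,0.77
TGC,C,0.23
CAA,Q,0.90
CAG,Q,0.10
GAA,E,0.88
GAG,E,0.12
GGT,G,0.58
GGA,G,0.27
GGC,G,0.10
GGG,G,0.05
CAT,H,0.79
CAC,H,0.21
ATT,I,0.61
ATA,I,0.24
ATC,I,0.15
TTA,L,0.48
TTG,L,0.22
CTT,L,0.13
CTA,L,0.08
CTC,L,0.06
CTG,L,0.03
AAA,K,0.89
AAG,K,0.11
ATG,M,1.00
TTT,F,0.84
TTC,F,0.16
CCA,P,0.55
CCT,P,0.28
CCC,P,0.10
CCG,P,0.07
TCA,S,0.33
TCT,S,0.23
AGT,S,0.18
TCC,S,0.10
TCG,S,0.10
AGC,S,0.06
ACA,T,0.44
ACT,T,0.33
ACC,T,0.15
ACG,T,0.08
TGG,W,1.00
TAT,Y,0.83
TAC,Y,0.17
GTT,V,0.48
GTA,V,0.25
GTC,V,0.12
GTG,V,0.15
TAA,*,0.85
TGA,*,0.10
TAG,*,0.05
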