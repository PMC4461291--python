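# Saccharomyces cerevisiae relative adaptiveness (w) for CAI,
# Sharp & Li (1987); the reference table distributed with CodonW,
# taken from the seqinr caitab dataset (column sc).
codon	w
AAA	0.135
AAC	1
AAG	1
AAT	0.053
ACA	0.012
ACC	1
ACG	0.006
ACT	0.921
AGA	1
AGC	0.031
AGG	0.003
AGT	0.021
ATA	0.003
ATC	1
ATG	1
ATT	0.823
CAA	1
CAC	1
CAG	0.007
CAT	0.245
CCA	1
CCC	0.009
CCG	0.002
CCT	0.047
CGA	0.002
CGC	0.002
CGG	0.002
CGT	0.137
CTA	0.039
CTC	0.003
CTG	0.003
CTT	0.006
GAA	1
GAC	1
GAG	0.016
GAT	0.554
GCA	0.015
GCC	0.316
GCG	0.001
GCT	1
GGA	0.002
GGC	0.02
GGG	0.004
GGT	1
GTA	0.002
GTC	0.831
GTG	0.018
GTT	1
TAA	0
TAC	1
TAG	0
TAT	0.071
TCA	0.036
TCC	0.693
TCG	0.005
TCT	1
TGA	0
TGC	0.077
TGG	1
TGT	1
TTA	0.117
TTC	1
TTG	1
TTT	0.113
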