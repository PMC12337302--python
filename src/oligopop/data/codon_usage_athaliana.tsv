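codon	amino_acid	frequency
GCT	A	0.44
GCC	A	0.16
GCA	A	0.26
GCG	A	0.14
CGT	R	0.17
CGC	R	0.07
CGA	R	0.12
CGG	R	0.09
AGA	R	0.35
AGG	R	0.20
AAT	N	0.52
AAC	N	0.48
GAT	D	0.68
GAC	D	0.32
TGT	C	0.60
TGC	C	0.40
CAA	Q	0.56
CAG	Q	0.44
GAA	E	0.52
GAG	E	0.48
GGT	G	0.34
GGC	G	0.14
GGA	G	0.37
GGG	G	0.15
CAT	H	0.61
CAC	H	0.39
ATT	I	0.41
ATC	I	0.35
ATA	I	0.24
TTA	L	0.13
TTG	L	0.22
CTT	L	0.26
CTC	L	0.17
CTA	L	0.11
CTG	L	0.11
AAA	K	0.49
AAG	K	0.51
ATG	M	1.00
TTT	F	0.51
TTC	F	0.49
CCT	P	0.38
CCC	P	0.11
CCA	P	0.33
CCG	P	0.18
TCT	S	0.28
TCC	S	0.13
TCA	S	0.20
TCG	S	0.10
AGT	S	0.16
AGC	S	0.13
ACT	T	0.34
ACC	T	0.20
ACA	T	0.30
ACG	T	0.16
TGG	W	1.00
TAT	Y	0.52
TAC	Y	0.48
GTT	V	0.41
GTC	V	0.19
GTA	V	0.14
GTG	V	0.26
TAA	*	0.36
TAG	*	0.20
TGA	*	0.44
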