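species	group	PKS;NRPS	NPS11/ETP mod 1	NPS12/ETP mod 2	NPS10	CYCLO	SID	ACV	AAR	EAS	Other
A. fumigatus	Euascomycota	1	2^c^	1	1	1	1	0	1	10	2
A. nidulans	Euascomycota	1	0	1	1	2^d^	1	1	1	11	0
B. cinerea	Euascomycota	3^e^	1	0	0	0	3	0	1	5	1
C. immitis	Euascomycota	1	0	0	0	0	1	0	1	5	0
C. heterostrophus	Euascomycota	0	1	2	1	2^d^	1	0	1	6	1
F. graminearum	Euascomycota	1	0	3	1	1	2	0	1	12	0
M. oryzae	Euascomycota	6	1	1	1	1^d^	1	0	1	4	2
N. crassa	Euascomycota	0	0	0	0	0	1	0	1	2	0
P. anserina	Euascomycota	4	0	1	0	0	1	0	1	4	1
T. reesii	Euascomycota	2	2^c^	1	1	0	1	0	1	5	0
C. cinerea	Basidiomycota	0	0	3	0	0	1	0	1	0	0
C. neoformans	Basidiomycota	0	0	0	0	0	0	0	1	0	0
L. bicolor	Basidiomycota	0	0	0	0	0	0	0	1	0	0
P. chrysosporium	Basidiomycota	0	0	1	0	1	0	0	1	0	0
P. stipitis	Basidiomycota	0	0	0	0	0	0	0	1	0	0
P. placenta	Basidiomycota	0	0	8	0	0	0	0	2	0	0
P. graminis	Basidiomycota	0	0	0	0	0	0	0	1	0	1
S. roseus	Basidiomycota	0	0	0	0	0	0	0	1	0	1
U. maydis	Basidiomycota	0	0	0	1	0	2	0	1	0	1
S. japonicus	Schizosaccharomycota	0	0	0	0	0	1	0	1	0	0
S. pombe	Schizosaccharomycota	0	0	0	0	0	1	0	1	0	0
Hemiascomycota_all	Hemiascomycota	0	0	0	0	0	0	0	1	0	0
P. blakesleeanus	Zygomycota	0	0	0	0	0	0	0	1	0	0
R. oryzae	Zygomycota	0	0	0	0	0	0	0	1	0	0
B. dendrobatidis	Chytridiomycota	0	0	2	0	0	0	0	1	0	0
E. cuniculi	Microsporidia	0	0	0	0	0	0	0	0	0	0
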