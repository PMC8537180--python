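label	ec	enzyme	substrate	product
MP	2.4.1.8	Maltose phosphorylase	Glca1->4Glc	bGlc1P
TP	2.4.1.64	Trehalose phosphorylase	Glca1->1aGlc	bGlc1P
T6PP	2.4.1.216	Trehalose-6-phosphate phosphorylase	Glca1->1aGlc6P	bGlc1P
KP	2.4.1.230	Kojibiose phosphorylase	Glca1->2Glc	bGlc1P
NP	2.4.1.279	Nigerose phosphorylase	Glca1->3Glc	bGlc1P
GRP	2.4.1.282	3-O-alpha-glucosyl-L-rhamnose phosphorylase	Glca1->3L-Rham	bGlc1P
GGP	2.4.1.332	2-O-alpha-glucosylglycerol phosphorylase	Glca1->2Glycerol	bGlc1P
oligoNP	2.4.1.334	alpha-1,3-oligoglucan phosphorylase	Glca1->(3Glca1->)n-2 3Glc	bGlc1P
TH	3.2.1.28	Trehalose hydrolase (trehalase)	Glca1->1aGlc	Glc
PGGHG	3.2.1.107	Protein-alpha-glucosyl-1,2-beta-galactosyl-L-hydroxylysine alpha-glucosidase	Glca1->2Galb1->5Hyl	Glc
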