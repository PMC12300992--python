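# Synthetic reduced stand-in for the Novartis NIBR structural-alert rules.
# The published NIBR set is not redistributable from any installed toolkit;
# this file holds a small hand-curated subset of widely recognized reactive,
# unstable, or toxicophoric motifs in the same spirit, for the cascade's
# NIBR-style stage. Format: SMARTS<tab>name, one per line.
[N+](=O)[O-]	nitro_group
C(=O)Cl	acyl_halide
S(=O)(=O)Cl	sulfonyl_halide
[CX4][Cl,Br,I]	alkyl_halide
C=[N+]=[N-]	diazo
N=[N+]=[N-]	azide
[NX2]=[NX2]	azo
O-O	peroxide
[SX2][SX2]	disulfide
C1OC1	epoxide
C1NC1	aziridine
[CX3](=O)[CX3](=O)	1_2_dicarbonyl
C=C[CX3]=O	michael_acceptor_enone
[CH1]=O	aldehyde
[N;!R]=[C;!R]	acyclic_imine
[C;!R](=S)	thiocarbonyl
[OX2][NX3]	o_n_single_bond
C(=O)OC(=O)	anhydride
S1C(=O)NC(=O)C1	rhodanine_like
[Se,Te,As,Sb,Si,Sn,Pb,Hg,Cd]	exotic_element
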