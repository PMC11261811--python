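# Residue-pair contact energies for scaffold binding-energy scoring
# (score units). Hydrophobic attraction by geometric-mean mixing of a
# hydropathy-derived strength, +/-0.25 per unit charge product, -0.10 for
# polar-polar side-chain H-bonding. Nominal parameterization of this
# package; swappable via PotentialTable.from_files.
res	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.1600	-0.1886	-0.0000	-0.0000	-0.2263	0.0000	0.0000	-0.2530	0.0000	-0.2325	-0.1644	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.2444	-0.2191	-0.1876
C	-0.1886	-0.2222	-0.0000	-0.0000	-0.2667	0.0000	0.0000	-0.2981	0.0000	-0.2740	-0.1937	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.2880	-0.2582	-0.2211
D	-0.0000	-0.0000	0.2500	0.2500	-0.0000	-0.0000	-0.0000	-0.0000	-0.2500	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.2500	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000
E	-0.0000	-0.0000	0.2500	0.2500	-0.0000	-0.0000	-0.0000	-0.0000	-0.2500	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.2500	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000
F	-0.2263	-0.2667	-0.0000	-0.0000	-0.3200	0.0000	0.0000	-0.3578	0.0000	-0.3288	-0.2325	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.3456	-0.3098	-0.2653
G	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
H	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	-0.1000	0.0000	0.0000	0.0000	0.0000	-0.1000	0.0000	-0.1000	0.0000	-0.1000	-0.1000	0.0000	0.0000	0.0000
I	-0.2530	-0.2981	-0.0000	-0.0000	-0.3578	0.0000	0.0000	-0.4000	0.0000	-0.3676	-0.2599	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.3864	-0.3464	-0.2966
K	0.0000	0.0000	-0.2500	-0.2500	0.0000	0.0000	0.0000	0.0000	0.2500	0.0000	0.0000	0.0000	0.0000	0.0000	0.2500	0.0000	0.0000	0.0000	0.0000	0.0000
L	-0.2325	-0.2740	-0.0000	-0.0000	-0.3288	0.0000	0.0000	-0.3676	0.0000	-0.3378	-0.2388	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.3551	-0.3183	-0.2726
M	-0.1644	-0.1937	-0.0000	-0.0000	-0.2325	0.0000	0.0000	-0.2599	0.0000	-0.2388	-0.1689	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.2511	-0.2251	-0.1928
N	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	-0.1000	0.0000	0.0000	0.0000	0.0000	-0.1000	0.0000	-0.1000	0.0000	-0.1000	-0.1000	0.0000	0.0000	0.0000
P	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
Q	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	-0.1000	0.0000	0.0000	0.0000	0.0000	-0.1000	0.0000	-0.1000	0.0000	-0.1000	-0.1000	0.0000	0.0000	0.0000
R	0.0000	0.0000	-0.2500	-0.2500	0.0000	0.0000	0.0000	0.0000	0.2500	0.0000	0.0000	0.0000	0.0000	0.0000	0.2500	0.0000	0.0000	0.0000	0.0000	0.0000
S	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	-0.1000	0.0000	0.0000	0.0000	0.0000	-0.1000	0.0000	-0.1000	0.0000	-0.1000	-0.1000	0.0000	0.0000	0.0000
T	0.0000	0.0000	-0.0000	-0.0000	0.0000	0.0000	-0.1000	0.0000	0.0000	0.0000	0.0000	-0.1000	0.0000	-0.1000	0.0000	-0.1000	-0.1000	0.0000	0.0000	0.0000
V	-0.2444	-0.2880	-0.0000	-0.0000	-0.3456	0.0000	0.0000	-0.3864	0.0000	-0.3551	-0.2511	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.3733	-0.3347	-0.2866
W	-0.2191	-0.2582	-0.0000	-0.0000	-0.3098	0.0000	0.0000	-0.3464	0.0000	-0.3183	-0.2251	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.3347	-0.3000	-0.2569
Y	-0.1876	-0.2211	-0.0000	-0.0000	-0.2653	0.0000	0.0000	-0.2966	0.0000	-0.2726	-0.1928	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	-0.2866	-0.2569	-0.2200
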