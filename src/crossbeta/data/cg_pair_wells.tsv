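# Side-chain pair square-well depths in units of the backbone H-bond
# well depth (positive = attractive, negative = repulsive shoulder).
# Hydrophobic geometric-mean mixing; screened electrostatics omitted
# (high-ionic-strength limit). Nominal values for this package's
# shipped parameter set.
res	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.2400	0.2828	0.0000	0.0000	0.3394	0.0000	0.0000	0.3795	0.0000	0.3487	0.2466	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.3666	0.3286	0.2814
C	0.2828	0.3333	0.0000	0.0000	0.4000	0.0000	0.0000	0.4472	0.0000	0.4110	0.2906	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.4320	0.3873	0.3317
D	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
E	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
F	0.3394	0.4000	0.0000	0.0000	0.4800	0.0000	0.0000	0.5367	0.0000	0.4932	0.3487	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.5185	0.4648	0.3980
G	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
H	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0500	0.0000	0.0500	0.0500	0.0000	0.0000	0.0000
I	0.3795	0.4472	0.0000	0.0000	0.5367	0.0000	0.0000	0.6000	0.0000	0.5514	0.3899	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.5797	0.5196	0.4450
K	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
L	0.3487	0.4110	0.0000	0.0000	0.4932	0.0000	0.0000	0.5514	0.0000	0.5067	0.3583	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.5327	0.4775	0.4089
M	0.2466	0.2906	0.0000	0.0000	0.3487	0.0000	0.0000	0.3899	0.0000	0.3583	0.2533	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.3767	0.3376	0.2891
N	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0500	0.0000	0.0500	0.0500	0.0000	0.0000	0.0000
P	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
Q	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0500	0.0000	0.0500	0.0500	0.0000	0.0000	0.0000
R	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
S	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0500	0.0000	0.0500	0.0500	0.0000	0.0000	0.0000
T	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0000	0.0000	0.0000	0.0500	0.0000	0.0500	0.0000	0.0500	0.0500	0.0000	0.0000	0.0000
V	0.3666	0.4320	0.0000	0.0000	0.5185	0.0000	0.0000	0.5797	0.0000	0.5327	0.3767	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.5600	0.5020	0.4299
W	0.3286	0.3873	0.0000	0.0000	0.4648	0.0000	0.0000	0.5196	0.0000	0.4775	0.3376	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.5020	0.4500	0.3854
Y	0.2814	0.3317	0.0000	0.0000	0.3980	0.0000	0.0000	0.4450	0.0000	0.4089	0.2891	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.4299	0.3854	0.3300
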