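# Additive per-residue intrinsic aggregation propensity scale
# (dimensionless): normalized Kyte-Doolittle hydropathy with an
# aromatic bonus. Zero-centered, so sequence sums may be negative.
res	value
A	0.4000
C	0.5556
D	-0.7778
E	-0.7778
F	1.1222
G	-0.0889
H	-0.7111
I	1.0000
K	-0.8667
L	0.8444
M	0.4222
N	-0.7778
P	-0.3556
Q	-0.7778
R	-1.0000
S	-0.1778
T	-0.1556
V	0.9333
W	0.3000
Y	0.2111
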