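# Coarse-grained bead parameters (nominal values assembled for this
# package; NOT the published force-field constants, which are
# configurable via this file). Backbone rows: NH, CA, CO united
# atoms. Side-chain rows: one bead per amino acid.
bead	diameter	mass	ca_r_bond
NH	3.30	15.02	-
CA	3.70	13.02	-
CO	4.20	28.01	-
R_A	2.60	15.03	1.55
R_C	3.40	47.10	1.85
R_D	3.50	59.04	1.90
R_E	3.80	73.07	2.10
R_F	4.40	91.13	2.35
R_G	2.00	1.01	1.20
R_H	4.00	81.10	2.25
R_I	3.90	57.11	2.05
R_K	4.20	72.13	2.35
R_L	3.90	57.11	2.05
R_M	4.00	75.15	2.20
R_N	3.60	58.06	1.95
R_P	3.60	41.07	1.85
R_Q	3.90	72.09	2.15
R_R	4.40	100.14	2.45
R_S	2.90	31.03	1.65
R_T	3.30	45.06	1.80
R_V	3.50	43.09	1.90
R_W	4.90	130.17	2.55
R_Y	4.50	107.13	2.45
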