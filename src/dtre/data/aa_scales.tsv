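residue	polarity_grantham	volume_zamyatnin	polarizability_charton	free_energy_charton	steric_charton	bulkiness_zimmerman	vdw_volume_norm	pI_residue
A	8.1	88.6	0.046	-0.368	0.52	11.50	1.00	6.00
R	10.5	173.4	0.291	-1.030	0.68	14.28	6.13	10.76
N	11.6	114.1	0.134	0.000	0.76	12.82	2.95	5.41
D	13.0	111.1	0.105	2.060	0.76	11.68	2.78	2.77
C	5.5	108.5	0.128	4.530	0.62	13.46	2.43	5.07
Q	10.5	143.8	0.180	0.731	0.68	14.45	3.95	5.65
E	12.3	138.4	0.151	1.770	0.68	13.57	3.78	3.22
G	9.0	60.1	0.000	-0.525	0.00	3.40	0.00	5.97
H	10.4	153.2	0.230	0.000	0.70	13.69	4.66	7.59
I	5.2	166.7	0.186	0.791	1.02	21.40	4.00	6.02
L	4.9	166.7	0.186	1.070	0.98	21.40	4.00	5.98
K	11.3	168.6	0.219	0.000	0.68	15.71	4.77	9.74
M	5.7	162.9	0.221	0.656	0.78	16.25	4.43	5.74
F	5.2	189.9	0.290	1.060	0.70	19.80	5.89	5.48
P	8.0	112.7	0.131	-2.240	0.36	17.43	2.72	6.30
S	9.2	89.0	0.062	-0.524	0.53	9.47	1.60	5.68
T	8.6	116.1	0.108	0.000	0.50	15.77	2.60	5.60
W	5.4	227.8	0.409	1.600	0.70	21.67	8.08	5.89
Y	6.2	193.6	0.298	4.910	0.70	18.03	6.47	5.66
V	5.9	140.0	0.140	0.401	0.76	21.57	3.00	5.96
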