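residue	mj_q	parallel_q	antiparallel_q	q_values	parallel_sheet_dg	antiparallel_sheet_dg
C	0.3775	0.3314	-0.1364	-1.3330	0.0685	-0.4569
F	-0.8575	-0.0677	-0.1439	-2.2031	-0.4304	-0.5163
L	-0.8635	-0.0037	0.2036	-2.2283	-0.3633	-0.0535
W	0.0220	0.3693	-0.1354	-1.4989	0.0069	-0.4696
V	0.0665	-0.5571	-0.2639	-1.5845	-1.0009	-0.6972
I	-0.4815	-0.5002	-0.1024	-1.9617	-0.9620	-0.5686
M	-0.0320	0.0258	0.1861	-1.6448	-0.1320	-0.0535
Y	0.4090	-0.0946	-0.3104	-1.1368	-0.2450	-0.6292
A	1.3140	0.4663	0.6531	-0.6288	0.1752	0.3474
P	0.0455	0.0304	0.0496	-0.2716	1.3643	1.0544
H	-0.5874	-0.4483	-0.3311	-0.5382	0.0008	0.0305
G	-0.1594	0.0632	0.2939	-0.2414	0.5167	0.5544
N	0.0891	0.1812	0.3249	-0.0553	0.7016	0.5942
T	-0.2749	-0.5853	-0.4491	-0.2917	-0.0449	-0.2755
S	0.0316	-0.1928	-0.1561	-0.0553	0.4718	0.1457
R	-0.0624	0.0532	-0.1831	-0.1006	0.5432	0.0133
Q	-0.0094	-0.0473	-0.1226	-0.1157	0.6694	0.1976
D	0.1986	0.4062	0.6719	0.2012	0.8437	0.7852
K	0.5506	0.2807	-0.1516	0.3270	0.6792	0.1447
E	0.2236	0.2892	0.1029	0.1408	0.7587	0.3565
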