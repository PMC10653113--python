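element	alpha1_au	c6_au	c8_ref_au	c10_ref_au	re_ref_bohr	de_ref_mev	family	source
He	1.38	1.46	14.123	183.79	5.608	0.948	noble_gas	alpha1,C6 ref64; C8,C10 ref65; Re,De CCSD(T) ref15
Ne	2.67	6.38	90.265	1532.8	5.83	3.632	noble_gas	alpha1,C6 ref64; C8,C10 ref65; Re,De CCSD(T) ref15
Ar	11.1	64.3	1621.5	49033	7.11	12.319	noble_gas	alpha1,C6 ref64; C8,C10 ref65; Re,De CCSD(T) ref15
Kr	16.8	129.6	4040	150130	7.589	17.310	noble_gas	alpha1,C6 ref64; C8,C10 ref65; Re,De CCSD(T) ref15
Xe	27.3	285.9	12004	588210	8.273	24.126	noble_gas	alpha1,C6 ref64; C8,C10 ref65; Re,De CCSD(T) ref15
Rn	33.54	420.6	19263	1067000	8.37	34.885	noble_gas	alpha1 ref64; C6*,C8*,C10* ref13 (starred); Re,De ref15
Mg	71.3	627			7.35	53.81	group_II	alpha1,C6 ref88; Re,De ref89
Ca	157.1	2121			8.13	130.18	group_II	alpha1,C6 ref88; Re,De ref89
Sr	197.2	3103			8.88	129.69	group_II	alpha1,C6 ref88; Re,De ref89
Ba	273.5	5160			9.43	169.36	group_II	alpha1,C6 ref88; Re,De ref89
Zn	38.67	359			7.23	28.64	group_II	alpha1 ref90; C6 ref86; Re,De ref91
Cd	46	686			7.32	40.91	group_II	alpha1 ref90; C6 ref86; Re,De ref91
Hg	33.9	392			6.95	48.60	group_II	alpha1 ref90; C6 ref86; Re,De ref92
H	4.50	6.50					other	free-atom reference values (Chu-Dalgarno), molecular mode
C	12.0	46.6					other	free-atom reference values (Chu-Dalgarno), molecular mode
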