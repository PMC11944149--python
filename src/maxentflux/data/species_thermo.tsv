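# Curated standard formation properties (I = 0, 298.15 K reference), kJ/mol.
# Values seeded from standard Alberty/Atkins-style tabulations; phosphate pK
# structure (pK1/pK2/pK3 = 2.15/7.20/12.35) encoded directly. This is a small
# stand-in table sufficient for the external metabolites of aerobic glucose
# growth plus the toy fixtures; it is not the source study's appendix table.
metabolite	species	dfG0_kJ_mol	dfH0_kJ_mol	charge	nH	phase
glc	glc_aq	-915.90	-1262.19	0	12	aqueous
h2o	h2o_l	-237.19	-285.83	0	2	aqueous
h2o	h2o_g	-228.57	-241.82	0	2	gas
o2	o2_aq	16.40	-11.70	0	0	aqueous
o2	o2_g	0.00	0.00	0	0	gas
co2	co2_aq	-385.97	-413.80	0	0	aqueous
co2	hco3_m	-586.77	-691.99	-1	1	aqueous
co2	co3_2m	-527.81	-677.14	-2	0	aqueous
co2	co2_g	-394.36	-393.50	0	0	gas
ac	acetate_m	-369.31	-486.01	-1	3	aqueous
ac	acetic_acid	-396.45	-485.76	0	4	aqueous
nh3	nh4_p	-79.31	-132.51	1	4	aqueous
nh3	nh3_aq	-26.50	-80.29	0	3	aqueous
po4	h3po4	-1149.57	-1288.30	0	3	aqueous
po4	h2po4_m	-1137.30	-1302.60	-1	2	aqueous
po4	hpo4_2m	-1096.10	-1299.00	-2	1	aqueous
po4	po4_3m	-1025.61	-1277.40	-3	0	aqueous
so4	so4_2m	-744.53	-909.27	-2	0	aqueous
so4	hso4_m	-755.91	-887.34	-1	1	aqueous
biomass	biomass_cmol	-67.00	-91.00	0	1.6	aqueous
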