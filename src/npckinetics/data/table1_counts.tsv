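# EM tomography count table: analyzed NE surface area (um^2, shrinkage-corrected)
# and counts of mature pores, assembly intermediates and ONM/INM fusion events per
# cell x region, at known times after anaphase onset. Transcribed from the typeset
# summary table of the source study (caption totals: 154 um^2 analyzed area,
# 1322 mature pores, 279 intermediates; 5 fusion events).
# Transcription notes:
#  * inner_core 36.3 min n_intermediate = 18: the plain-text rendering of the table
#    drops one digit here ("8"); 18 is the unique single-digit repair that restores
#    the caption total of 279 intermediates (digit-sum mod 9 argument) and the ~50%
#    early-G1 inner-core intermediate fraction quoted in the text.
#  * fusion-event column placement is not recoverable from the plain-text rendering;
#    row sums (inner_core 3, outer_core 2) are authoritative, the times below are a
#    documented convention. No analysis depends on fusion timing.
#  * the two ">180 min" cells are stored as region=mature_ne at time_ao=181; they
#    enter only steady-state pooling, never kinetic fits, so only ordering matters.
cell_id	time_ao	region	area_um2	n_mature	n_intermediate	n_fusion
c01	19.2	non_core	5.29	82	2	0
c01	19.2	inner_core	5.77	24	21	0
c01	19.2	outer_core	4.22	29	23	0
c02	24.4	non_core	4.04	45	4	0
c02	24.4	inner_core	5.06	16	13	0
c02	24.4	outer_core	4.15	40	10	0
c03	28.4	non_core	5.06	48	6	0
c03	28.4	inner_core	4.16	3	12	0
c03	28.4	outer_core	3.83	27	19	0
c04	36.3	non_core	3.99	42	3	0
c04	36.3	inner_core	4.74	18	18	0
c04	36.3	outer_core	2.55	17	9	0
c05	42.0	non_core	5.17	62	5	0
c05	42.0	inner_core	6.75	30	35	2
c05	42.0	outer_core	4.78	44	13	0
c06	53.2	non_core	5.54	51	8	0
c06	53.2	inner_core	4.33	16	12	1
c06	53.2	outer_core	4.41	35	11	2
c07	61.0	non_core	4.04	53	3	0
c07	61.0	inner_core	3.61	34	1	0
c07	61.0	outer_core	3.59	38	1	0
c08	65.6	non_core	3.72	33	3	0
c08	65.6	inner_core	4.57	27	3	0
c08	65.6	outer_core	3.68	28	4	0
c09	73.6	non_core	3.06	33	2	0
c09	73.6	inner_core	4.07	27	4	0
c09	73.6	outer_core	2.71	30	1	0
c10	82.9	non_core	3.73	39	1	0
c10	82.9	inner_core	3.53	39	3	0
c10	82.9	outer_core	2.67	34	3	0
c11	100	non_core	3.32	33	5	0
c11	100	inner_core	4.61	53	2	0
c11	100	outer_core	2.77	25	5	0
c12	116	non_core	3.17	31	5	0
c12	116	inner_core	3.46	32	3	0
c12	116	outer_core	2.68	28	1	0
c13	181	mature_ne	4.03	45	4	0
c14	181	mature_ne	2.80	31	1	0
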