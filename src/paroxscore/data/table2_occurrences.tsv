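gene	variant_id	participant_id	category	consequence	zygosity	coseg_group	plp	cc_code
ATP1A2	p.Glu492Lys	1	other	missense	het		0
CACNA1A	p.Ala454Thr	1	other	missense	het		0
CACNA1A	p.Ala454Thr	11	other	missense	het		0
CACNA1A	p.Arg68Gln	76	other	missense	het		0
CACNA1A	p.Arg2294Pro	74	other	missense	het		0
CACNA1A	p.Arg2298Pro	43	other	missense	het		0
CACNA1A	p.Arg2298Pro	75	other	missense	het		0
CACNA1A	CAG_7	5	other	repeat_expansion	het		0
CACNA1A	CAG_7	8	other	repeat_expansion	het		0
CACNA1A	CAG_7	27	other	repeat_expansion	het		0
CACNA1A	CAG_7	30	other	repeat_expansion	het		0
CACNA1A	CAG_7	52	other	repeat_expansion	hom		0
CACNA1A	CAG_7	55	other	repeat_expansion	het		0
CACNA1A	CAG_7	67	other	repeat_expansion	het		0
CACNA1A	CAG_7	76	other	repeat_expansion	het		0
CACNA1A	CAG_7	80	other	repeat_expansion	hom		0
CACNA1A	CAG_4	31	other	repeat_expansion	het		0
CACNA1A	CAG_4	70	other	repeat_expansion	het		0
CACNA1A	p.Tyr2228Asn	50	other	missense	het		0
CACNA1A	p.Arg2135His	46	other	missense	het		0
CACNA1S	p.Ser516Leu	30	key	missense	het		0	PP
CACNA1S	p.Thr1335Ser	72	key	missense	het		0	EP_FATIGUE
CACNA1S	p.Thr1354Ser	16	key	missense	het		0	PP
CACNA1S	p.Val1253Ala	23	key	missense	het		0	PP
CACNA1S	p.Ala814Thr	69	other	missense	het		0
CACNA1S	p.Tyr299His	69	other	missense	het		0
CACNA1S	p.Cys288Gly	32	other	missense	het		0
CACNA1S	p.Pro1839Ser	14	other	missense	het		0
CACNA1S	p.Ser1857Asn	43	other	missense	het		0
CHAMP1	p.Pro406Ser	25	other	missense	het		0
CLCN1	p.Thr736Ile	68	key	missense	het		0	EP_WEAKNESS
GFAP	p.Asp157Asn	48	other	missense	het		0
GFAP	p.Pro47Leu	35	other	missense	het		0
GFAP	p.Pro47Leu	76	other	missense	het		0
KCNJ18	p.Gln407*	37	key	nonsense	het		1	PP
MEFV	p.Ala744Ser	53	key	missense	het		1
MEFV	p.Ile591Thr	65	key	missense	het		0	PAROX_ABD_PAIN
MEFV	p.Val726Ala	5	key	missense	het	MEFV_5	0	NEUROPATHIC_PAIN
MEFV	c.*381T>C	5	key	utr	het	MEFV_5	0	NEUROPATHIC_PAIN
MEFV	p.Pro369Ser	36	other	missense	het		0
MEFV	p.Pro369Ser	66	other	missense	het		0
MEFV	p.Arg408Gln	66	other	missense	het		0
OPRM1	p.Cys192Phe	2	other	missense	het		0
OPRM1	p.Cys192Phe	34	other	missense	het		0
OPRM1	p.Cys192Phe	73	other	missense	het		0
OPRM1	p.Ser147Cys	53	other	missense	het		0
OPRM1	p.Ser451Phe	11	other	missense	het		0
PDHA1	p.Met320Leu	28	other	missense	het		0
PNKD	p.Glu307Lys	43	other	missense	het		0
POGZ	p.Cys652Arg	18	key	missense	het		0	NDD
POGZ	p.Phe806Leu	77	key	missense	het		0	ASD
POGZ	p.Lys871Asn	27	other	missense	het		0
POLG	p.Lys460_Leu463del	74	key	inframe_indel	het		1
POLG	p.Arg42_Gln43insGln	38	other	inframe_indel	het		0
POLG	p.Gly268Ala	9	other	missense	het		0
POLG	p.Gly268Ala	18	other	missense	het		0
POLG	p.Gly517Val	38	other	missense	het		0
POLG	p.Gly517Val	52	other	missense	het		0
POLG	p.Gly517Val	58	other	missense	het		0
PPM1D	p.Tyr401fs	56	key	frameshift	het		1	NDD
PRRT2	p.Pro216Leu	41	other	missense	het		0
PRRT2	p.Pro216Leu	42	other	missense	het		0
PRRT2	p.Pro216Leu	54	other	missense	het		0
RYR2	p.Tyr3459*	54	key	nonsense	het		1
RYR2	p.Glu4431Lys	44	key	missense	het		0	CHRONIC_PAIN_GI
RYR2	p.Gly2094Ser	53	key	missense	het		0	PANIC
RYR2	p.Arg3567Cys	9	other	missense	het		0
RYR2	p.Arg4573His	35	other	missense	het		0
RYR2	p.Asn4736Asp	34	other	missense	het		0
RYR2	p.Gly1885Glu	4	other	missense	het		0
RYR2	p.Ser2829Gly	75	other	missense	het		0
RYR2	p.Thr1107Met	15	other	missense	het		0
SCN1A	p.Arg1928Gly	80	key	missense	het		0	ICE_PICK_MIGRAINE
SCN1A	p.Ile1437Val	29	other	missense	het	SCN1A_29	0
SCN1A	p.Ile1452Val	29	other	missense	het	SCN1A_29	0
SCN1A	p.Ile1465Val	29	other	missense	het	SCN1A_29	0
SCN2A	p.Ile403Thr	58	other	missense	het		0
SCN2A	p.Thr674Ala	58	other	missense	het		0
SCN4A	p.Ala488Thr	68	key	missense	het		0	EP_WEAKNESS
SCN4A	p.His599Arg	61	key	missense	het		0	PP
SCN4A	p.His599Arg	76	key	missense	het		0	PP
SCN4A	p.Ser906Thr	63	key	missense	het		0	PP
SCN4A	p.Arg1408Cys	45	other	missense	het		0
SCN4A	p.Lys477Arg	49	other	missense	het		0
SCN4A	p.Thr323Met	50	other	missense	het		0
SCN4A	p.Ser906Thr	15	other	missense	het		0
SCN4A	p.Ser906Thr	25	other	missense	het		0
SCN4A	p.Ser906Thr	52	other	missense	het		0
SCN4A	p.Ser906Thr	73	other	missense	het		0
SCN4A	p.Ser906Thr	78	other	missense	het		0
SCN9A	p.Asn1256Ser	9	key	missense	het		0	MIGRAINE_AURA
SCN9A	p.Ser802Gly	27	key	missense	het		0	MIGRAINE_AURA
SCN9A	p.Val1726Phe	7	other	missense	het		0
SCN9A	p.Val1715Phe	9	other	missense	het		0
SCN10A	p.Ala123Val	64	key	missense	het		0	CRPS
SCN10A	p.Arg14Leu	47	key	missense	het		0	WIDESPREAD_PAIN
SCN10A	p.Val1697Ile	27	key	missense	het		0	MIGRAINE_AURA
SCN11A	p.Gly1736Val	50	other	missense	het		0
SLC1A3	p.Arg47Gln	77	other	missense	het		0
TNFRSF1A	p.Arg121Gln	14	key	missense	het		1
TNFRSF1A	p.Arg121Gln	60	key	missense	het		1
TNFRSF1A	p.Arg121Gln	68	key	missense	het		1
TNFRSF1A	p.Pro75Leu	69	other	missense	het		0
TRAP1	p.Ile253Val	18	key	missense	het		1
TRAP1	p.Arg128His	60	key	missense	het		0	FATIGUE_PAIN_GI
TRAP1	p.Arg469Cys	7	other	missense	het		0
TRAP1	p.Asp685Asn	39	other	missense	het		0
TRAP1	p.Arg469His	39	other	missense	het		0
TRAP1	p.Gln165Glu	14	other	missense	het		0
TRAP1	p.Gly445Ser	3	other	missense	het		0
TRAP1	p.Ser477_Gly478insAla	3	other	inframe_indel	het		0
TRAP1	p.Ser477_Gly478insAla	76	other	inframe_indel	het		0
TRAP1	p.Tyr444Asn	51	other	missense	het		0
TRPA1	p.Ala138Ser	49	key	missense	het		0	EP_DIAPHRAGM_PAIN
TRPA1	p.Met214Thr	52	key	missense	het		0	EP_PAIN
TRPA1	p.Asn109Lys	2	other	missense	het		0
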