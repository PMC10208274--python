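gene	variant_id	participant_id	heteroplasmy_pct	n_domains	domain_labels	clinvar_lp	structure_exception	category
ATP6	m.8939T>C	53		6		0	0	key
COX2	m.7673A>G	20		6		0	0	key
COX2	m.7761A>G	33		6		0	0	key
COX3	m.9738G>A	14		1		0	0	other
CYB	m.15740C>T	74	94	6		0	0	key
CYB	m.15884G>A	12		3		0	0	other
ND1	m.3565A>C	42		1		0	0	other
ND5	m.12706T>C	39		6		1	0	key
TA	m.15904C>T	19	39	5		0	1	key
TG	m.10003T>C	51		2		0	0	other
TM	m.4464A>G	25		2		0	0	other
TR	m.10410T>A	39		4		0	1	key
TT	m.15907A>G	41		4		0	1	key
MT-MULTI	del_m.492-14240	73	46	5		0	0	key
MT-MULTI	del_m.6468-14148	P_UNNUMBERED		6		0	0	key
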