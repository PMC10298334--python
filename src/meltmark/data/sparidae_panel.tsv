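species	sample_id	region	fao_region	n_total	n_fc	n_fm_sm	n_re	n_frozen	n_cooked
P. pagrus	PpG	CY	37.3.1	12	12				2
P. pagrus	PpG	SP	37.3.1	25	24	1		1	3
P. pagrus	PpG	SG	37.3.1	11	10		1		2
P. pagrus	PpG	DO	37.3.1	10	8	2			2
P. pagrus	PpG	CR	37.3.1	3	2	1			2
P. pagrus	PpG	TG	37.3.1	1	1			1	1
P. pagrus	PpG	CM	37.3.1	1	1				1
P. pagrus	PpG	IO	37.2.2	8	8			1	2
P. pagrus	PpI	IMP	34.1	10		10		9	3
P. pagrus	PpM	ME	37.1.1	3	3			3	
P. major	Pm	AQ		16		14	2	2	2
P. major	Pm	LFT		3		3			2
P. major	Pm	CR	37.1.1	1	1			1	1
P. major	Pm	SP	37.1.1	1	1			1	1
P. caeruleostictus	Pc	IMP		1		1		1	1
P. erythrinus	Pe	SP	37.1.1	2	1	1			2
P. erythrinus	Pe	DO	37.1.1	8	4	3			3
P. erythrinus	PeI	IMP	34.1	1		1		1	1
D. dentex	DdG	CY	37.3.1	6	4	1	1		2
D. dentex	DdG	SP	37.3.1	3	2	1			1
D. dentex	DdG	SG	37.3.1	7	5	1	1		2
D. dentex	DdG	DO	37.3.1	2	2				2
D. dentex	DdG	CR	37.3.1	6	6				4
D. dentex	DdG	NA	37.3.1	4	4				2
D. dentex	DdG	IO	37.2.2	29	29				6
D. dentex	DdM	ME	37.1.1	3	3			3	
D. gibbosus	Dg	SP		2	1	1		1	1
D. gibbosus	Dg	CY		3	1	2			1
D. gibbosus	Dg	IO		2	1	1		2	1
D. gibbosus	Dg	SG		2			2	1	1
D. gibbosus	DgI	IMP	34.1	3		3		3	2
D. angolensis	Da	IMP	34.1	2		2			1
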