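patient	timepoint	dppi_percent	recommended_intervention	procedure	outcome	intervention_true
1	2	20	Yes	Cystoscopy	Cystitis	Yes
1	3	-80	No	Medical monitoring	No tumour	Yes
1	4	-61	No	Medical monitoring	No tumour	Yes
2	2	99	Yes	Cystoscopy/Re-TURBT	Tis stage recurrence	Yes
2	3	35	Yes	Cystoscopy/TURBT	T1 stage recurrence	Yes
2	4	5	Yes	Cystoscopy	Recurrence (no AP exam)	Yes
2	5	95	Yes	Medical monitoring	Recurrence (no AP exam)	Yes
3	2	36	Yes	Cystoscopy/Re-TURBT	T2 stage recurrence	Yes
3	3	-63	No	Medical monitoring	No recurrence	Yes
3	4	-79	No	Medical monitoring	No recurrence	Yes
4	2	-80	No	Medical monitoring	No recurrence	Yes
4	3	-56	No	Medical monitoring	No recurrence	Yes
5	2	-3	Yes	Cystoscopy/Re-TURBT	Ta stage recurrence	Yes
5	3	-2	Yes	Medical monitoring	Nonneoplastic bladder mass	Yes
6	2	-41	No	Cystoscopy	No recurrence	Yes
6	3	-7	No	Medical monitoring	No recurrence	Yes
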