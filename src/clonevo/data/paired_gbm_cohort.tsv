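# Clinical metadata for the 21-patient paired primary/recurrent GBM cohort.
# treatment_detail "none" marks patients who received no intervention other
# than surgery before the second resection.
patient_id	gender	age_at_diagnosis	primary_diagnosis	recurrence_diagnosis	treatment_detail	time_to_recurrence_months	survival_months
1	F	50	GBM	GBM	none	19	36.4
2	F	44	GBM	GBM	Concomitant RT/TMZ only	3	22.0
3	M	49	GBM	GBM	Concomitant RT/TMZ and 4 cycles adjuvant TMZ	8	9.9
4	M	35	GBM-PNC	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	11	12.2
7	F	62	GBM	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	7	11.9
8	M	33	GBM	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	9	18.6
9	M	51	GBM	GBM	Concomitant RT/TMZ and adjuvant AVAglio (+/-BVZ)	9	16.4
10	M	57	GBM	GBM	Concomitant RT/TMZ and 2 cycles adjuvant AVAglio (+/-BVZ)	5	17.1
11	M	74	GBM	GBM	Concomitant RT/TMZ only	3	7.2
12	M	66	GBM	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	11	15.9
14	M	56	GBM	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	14	17.6
15	F	33	GBM	GBM	Concomitant RT/TMZ only	8	14.6
16	M	39	GBM	GBM	Concomitant RT/TMZ and 4 cycles adjuvant TMZ	9	14.5
18	F	63	GBM	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	7	14.3
19	M	67	GBM	GS	Concomitant RT/TMZ and standard adjuvant TMZ, then 2nd line BVZ 8 months	18	19.5
20	F	57	GBM	GBM	Concomitant RT/TMZ and 9 cycles adjuvant AVAglio (+/-BVZ)	15	19.3
21	F	48	GBM-PNC	GBM-PNC	Concomitant RT/TMZ and standard adjuvant TMZ	24	29.2
22	M	43	GBM	GBM	Concomitant RT/TMZ and 4 cycles adjuvant TMZ	10	15.1
26	M	66	GBM	GBM	Concomitant RT/TMZ and standard adjuvant TMZ	8	30.6
28	M	54	GBM	GBM	none	2	13.2
29	M	34	GBM	GBM	none	3	13.8
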