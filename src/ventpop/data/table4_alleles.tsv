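strain	st_published	atpA	dnaK	gyrB	metG	napA	tkt	site	region
MT-17	1	1	1	1	1	2	2	urashima	SMT
MT-18	1	1	1	1	1	2	2	urashima	SMT
MT-31	2	1	7	6	3	3	3	archaean	SMT
MT-33	3	1	2	2	1	4	3	archaean	SMT
MT-22	4	1	11	12	11	10	14	snail	SMT
MT-11	5	2	4	2	4	5	5	urashima	SMT
MT-28	6	2	5	3	10	4	12	archaean	SMT
MT-12	7	2	10	11	5	5	13	urashima	SMT
MT-25	8	2	2	3	6	5	3	archaean	SMT
MT-10	9	2	2	19	1	15	2	urashima	SMT
MT-6	10	2	13	15	5	5	16	urashima	SMT
MT-9	11	2	4	2	4	14	21	urashima	SMT
MT-35	12	3	4	3	4	3	4	pika	SMT
MT-27	13	3	5	3	4	3	8	archaean	SMT
MT-16	14	4	6	4	4	13	6	urashima	SMT
MT-13	15	4	6	4	4	6	6	urashima	SMT
MT-15	16	4	14	4	4	6	19	urashima	SMT
MT-20	17	5	3	16	2	2	17	urashima	SMT
MT-21	18	5	15	18	2	2	2	urashima	SMT
MT-7	19	6	2	3	1	1	4	urashima	SMT
MT-8	20	6	2	3	1	1	20	urashima	SMT
MT-29	21	7	2	5	7	1	1	archaean	SMT
MT-19	22	8	3	1	2	2	2	urashima	SMT
MT-32	23	9	8	7	8	4	4	archaean	SMT
MT-23	25	10	4	8	1	8	9	snail	SMT
MT-24	26	11	2	9	9	9	10	snail	SMT
MT-36	27	12	9	10	1	3	11	pika	SMT
MT-30	28	13	12	3	1	11	5	archaean	SMT
MT-26	30	14	2	13	6	12	1	archaean	SMT
MT-14	31	15	4	3	3	3	3	urashima	SMT
MT-34	32	16	4	17	1	3	18	archaean	SMT
OT-1	33	17	16	20	12	7	22	iheya_north	OT
OT-2	34	18	17	21	13	16	23	iheya_north	OT
OT-4	35	19	18	22	14	7	24	iheya_north	OT
OT-3	36	20	19	23	15	17	7	iheya_north	OT
OT-5	37	21	20	14	16	18	15	hatoma_knoll	OT
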