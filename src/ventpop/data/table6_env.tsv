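site	region	sampling_year	tmax_c	ph	cl_mmol_kg	na_mmol_kg	k_mmol_kg	ca_mmol_kg	mn_umol_kg	nh4_umol_kg	so4_mmol_kg	h2s_mmol_kg
iheya_north	OT	2007	309	5.0	557	407	72.4	21.9	658	1710	0
hatoma_knoll	OT	2000	240	5.2	381	285	54.6	17.0	483	7200
urashima	SMT	2010	280	3.0	623	456	37.0	31.9	2220		-4.11	2.4
snail	SMT	2010	61	3.5	558	442	28.4	28.0	1840		-0.41	2.0
archaean	SMT	2010	318	3.0	401	312	33.0	15.8	1280		-0.24	9.6
pika	SMT	2010	322	3.0	469	444	31.6	37.8	1140		-2.98	7.0
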