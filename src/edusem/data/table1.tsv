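variable	age11_mht	education	logical_memory	digit_symbol	matrix_reasoning	block_design	verbal_paired_assoc	symbol_search	letter_number_seq	digit_span_backwards	spatial_span	age70_mht	mean	sd	n
age11_mht	1												49.00	11.40	1,028
education	.42	1											10.74	1.13	1,091
logical_memory	.43	.31	1										71.37	17.95	1,087
digit_symbol	.44	.30	.31	1									56.60	12.93	1,086
matrix_reasoning	.46	.31	.33	.37	1								13.49	5.13	1,086
block_design	.46	.31	.28	.39	.57	1							33.79	10.32	1,085
verbal_paired_assoc	.32	.22	.48	.24	.31	.27	1						26.44	9.13	1,050
symbol_search	.47	.27	.33	.62	.45	.48	.22	1					24.71	6.39	1,086
letter_number_seq	.45	.25	.40	.41	.44	.40	.30	.45	1				10.92	3.16	1,079
digit_span_backwards	.42	.21	.30	.30	.40	.34	.27	.34	.54	1			7.74	2.26	1,090
spatial_span	.28	.14	.24	.31	.38	.40	.16	.41	.42	.32	1		14.72	2.83	1,084
age70_mht	.67	.39	.46	.49	.58	.51	.35	.53	.51	.40	.36	1	64.28	8.64	1,078
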