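genome	target	region	subfamily	evalue	bit_score	best
skate	AESE012567234.1	TM1-4	Type I	4.7E-28	107.9	0
skate	AESE012567234.1	TM1-4	Type IIa-1	7.1E-50	178.5	1
skate	AESE012567234.1	TM1-4	Type IIa-2	1.7E-47	107.7	0
skate	AESE012567234.1	TM1-4	Type IIa-3	5.0E-41	149.8	0
skate	AESE012567234.1	TM1-4	Type IIb	8.1E-41	149.0	0
skate	AESE011658775.1	TM1-4	Type I	1.1E-34	129.2	0
skate	AESE011658775.1	TM1-4	Type IIa-1	2.4E-60	212.4	0
skate	AESE011658775.1	TM1-4	Type IIa-2	8.5E-68	236.5	1
skate	AESE011658775.1	TM1-4	Type IIa-3	7.2E-64	223.8	0
skate	AESE011658775.1	TM1-4	Type IIb	2.1E-50	180.0	0
skate	AESE011105720.1	TM1-4	Type I	3.4E-48	173.2	1
skate	AESE011105720.1	TM1-4	Type IIa-1	3.9E-43	127.5	0
skate	AESE011105720.1	TM1-4	Type IIa-2	1.5E-31	199.1	0
skate	AESE011105720.1	TM1-4	Type IIa-3	2.2E-32	121.8	0
skate	AESE011105720.1	TM1-4	Type IIb	2.9E-35	131.0	0
skate	AESE010056425.1	TM6-7	Type I	1.3E-19	79,9	0
skate	AESE010056425.1	TM6-7	Type IIa-1	5.5E-33	122.6	1
skate	AESE010056425.1	TM6-7	Type IIa-2	1.0E-25	99.5	0
skate	AESE010056425.1	TM6-7	Type IIa-3	3.6E-25	97.7	0
skate	AESE010056425.1	TM6-7	Type IIb	1.6E-23	92.2	0
skate	AESE011520245.1	TM6-7	Type I	9.3E-29	109.2	0
skate	AESE011520245.1	TM6-7	Type IIa-1	3.5E-33	123.2	0
skate	AESE011520245.1	TM6-7	Type IIa-2	1.3E-40	147.3	1
skate	AESE011520245.1	TM6-7	Type IIa-3	5.1E-39	142.1	0
skate	AESE011520245.1	TM6-7	Type IIb	2.5E-21	117.2	0
skate	AESE012567234.1	TM6-7	Type I	1.8E-38	140.4	1
skate	AESE012567234.1	TM6-7	Type IIa-1	6.73E-3	119.1	0
skate	AESE012567234.1	TM6-7	Type IIa-2	1.4E-30	115.1	0
skate	AESE012567234.1	TM6-7	Type IIa-3	9.3E-28	106.0	0
skate	AESE012567234.1	TM6-7	Type IIb	2.1E-32	120.6	0
lamprey	22569.4_6	TM1-4	Type I	1.2E-44	138	0
lamprey	22569.4_6	TM1-4	Type IIa-1	3.4E-75	237	1
lamprey	22569.4_6	TM1-4	Type IIa-2	7.3E-61	191	0
lamprey	22569.4_6	TM1-4	Type IIa-3	2.9E-59	185	0
lamprey	22569.4_6	TM1-4	Type IIb	2.5E-54	169	0
lamprey	42790.2_1	TM1-4	Type I	1.0E-33	103	0
lamprey	42790.2_1	TM1-4	Type IIa-1	2.5E-59	186	1
lamprey	42790.2_1	TM1-4	Type IIa-2	1.2E-49	154	0
lamprey	42790.2_1	TM1-4	Type IIa-3	6.9E-47	145	0
lamprey	42790.2_1	TM1-4	Type IIb	9.7E-46	141	0
lamprey	31731.1_3	TM1-4	Type I	1.9E-23	69	0
lamprey	31731.1_3	TM1-4	Type IIa-1	1.7E-41	128	1
lamprey	31731.1_3	TM1-4	Type IIa-2	7.3E-34	103	0
lamprey	31731.1_3	TM1-4	Type IIa-3	3.0E-32	97	0
lamprey	31731.1_3	TM1-4	Type IIb	2.5E-31	95	0
lamprey	30359.1_1	TM6-7	Type I	3.7E-36	110	0
lamprey	30359.1_1	TM6-7	Type IIa-1	6.7E-48	138	1
lamprey	30359.1_1	TM6-7	Type IIa-2	4.5E-39	119	0
lamprey	30359.1_1	TM6-7	Type IIa-3	4.9E-38	116	0
lamprey	30359.1_1	TM6-7	Type IIb	9.5E-37	111	0
lamprey	36401.1_5	TM6-7	Type I	7.2E-30	90	0
lamprey	36401.1_5	TM6-7	Type IIa-1	3.6E-45	138	1
lamprey	36401.1_5	TM6-7	Type IIa-2	1.2E-32	98	0
lamprey	36401.1_5	TM6-7	Type IIa-3	1.3E-32	98	0
lamprey	36401.1_5	TM6-7	Type IIb	3.0E-33	100	0
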