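base	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11	p12	p13	p14	p15
A	10	9	8	9	8	9	9	9	10	10	24	4	100	0	25
C	30	31	32	33	34	35	36	37	38	39	30	75	0	0	15
G	15	14	13	12	12	11	10	9	9	8	21	1	0	100	50
T	45	46	47	46	46	45	45	45	43	43	25	20	0	0	10
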