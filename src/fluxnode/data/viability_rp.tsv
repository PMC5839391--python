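cell_line	0	156.25	312.5	625	1250	2500	5000	10000
MCF7	100.00	29.36	22.34	31.62	19.88	16.29	7.53	3.32
T47D	100.00	33.02	33.76	43.74	24.39	17.73	8.69	11.15
CAMA1	100.00	70.22	46.25	45.99	26.28	22.46	13.45	7.71
MDAMB231	100.00	79.92	82.09	67.84	62.16	62.43	31.95	24.50
MDAMB468	100.00	48.25	48.51	71.92	75.75	52.74	55.31	4.49
HCC1143	100.00	125.74	136.39	137.53	144.66	130.58	85.55	24.85
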