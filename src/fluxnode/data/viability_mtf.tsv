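cell_line	0	5	10	20	40	80	160
MCF7	100.00	135.07	95.00	61.49	30.61	28.36	2.47
T47D	100.00	85.74	70.15	59.87	42.11	7.10	0.00
CAMA1	100.00	88.08	112.76	93.70	108.67	63.25	3.49
MDAMB231	100.00	65.08	58.36	57.78	37.82	11.45	1.77
MDAMB468	100.00	40.05	55.39	21.82	1.31	1.71	0.00
HCC1143	100.00	105.48	85.25	73.19	52.89	20.49	0.00
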