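# Cross-linked products of the PSI-LHCI supercomplex (packaged fixture).
# Columns: record_id, members (semicolon list), apparent_kd (n.d. = not
# determined), linkers (comma list), methods (I = immunoblot, M = mass
# spectrometry).
record_id	members	apparent_kd	linkers	methods
1	LHCA1;LHCA9	42	DSS,DSG	I
2	LHCA1;PSAG	31	DSG	I
3	LHCA2;LHCA9	43	DSS,DSG	I
4	LHCA2;LHCA9;PSAG	53	DSS	I
5	LHCA2;PSAH	n.d.	DSS	M
6	LHCA2;PSAB	n.d.	DSS	M
7	LHCA3;PSAK	32	DSS	I,M
8	LHCA4;LHCA8	48	DSS,DSG	I,M
9	LHCA5;LHCA3	47	DSS	I
10	LHCA5;LHCA6	47	DSS,DSG	I
11	LHCA3;LHCA7	46	DSS	I
12	LHCA7;LHCA8	44	DSS	I
13	LHCA7;PSAN	31	EDC	I
14	LHCA8;PSAN	31	EDC	I
15	LHCA8;PSAF	40	DSS,DSG	I
16	LHCA9;PSAG	31	DSS,EDC	I
17	PSAA;PSAF	n.d.	DSS	M
18	PSAB;PSAD	n.d.	DSS	M
19	PSAD;PSAF	n.d.	DSS	M
20	PSAF;PSAN	27	EDC	I
21	PSAL;PSAO	22	EDC,DSG	I
22	PSAH;PSAO	20	DMS	I
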