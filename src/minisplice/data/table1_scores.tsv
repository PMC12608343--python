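variant	protein	exon	gnomad_af	ds_ag	ds_al	ds_dg	ds_dl	spip_interpretation	spip_bp	spip_confidence	mmsplice_dlp	alphamissense
c.158G>A	p.Arg53Gln	3	0.00003107	0.01	0.18	0	0.27	Alter by create New splice site + Alter ESR	No	85.91	-0.41	0.77
c.174A>T	p.Arg58Ser	3	0	0	0.02	0.91	0.71	Alter by SPiCE + Alter ESR	No	98.11	-2.62	0.97
c.177-35T>G		4	0	0	0.02	0	0.02	Alter BP	Yes	10.53	-0.40
c.342+3A>C		5	0.000003728	0	0.01	0.32	0.84	Alter by SPiCE	No	98.41	-3.85
c.342+9G>T		5	0.0000006227	0.01	0.01	0.08	0.23	NTR	No	0.72	0.33
c.343-6T>A		6	0.00002737	0.01	0.1	0	0.05	Alter by SPiCE	No	54	-1.48
c.343G>C	p.Gly115Arg	6	0.00004528	0.02	0.08	0.01	0.02	Alter by SPiCE	No	69.33	-0.79	0.89
c.433A>T	p.Arg145Ter	6	0	0.01	0.03	0.01	0.01	Alter by SPiCE	No	54	-1.10
c.455G>C	p.Gly152Ala	7	0.000003101	0.23	0	0.18	0	NTR	No	8.04	1.10	0.51
c.469+5G>A		7	0	0	0.6	0	0.75	Alter by SPiCE	No	98.41	-3.82
c.469+6T>C		7	0	0	0.49	0	0.61	Alter by SPiCE	No	85.91	-0.97
c.469G>T	p.Val157Phe	7	0.000001862	0	0.58	0	0.7	Alter by SPiCE	No	98.41	-2.48	0.87
c.549G>T	p.Gln183His	8	0.0000031	0.01	0.42	0.11	0.75	Alter by SPiCE	No	98.41	-4.09	0.88
c.612T>C	p.Tyr204=	9	0.000003099	0.2	0	0.21	0	Alter by complex event	No	26.62	0.34
c.624T>C	p.Phe208=	9	0.00000248	0.21	0	0.25	0	NTR	No	7.62	0.51
c.649G>T	p.Gly217Trp	9	0	0	0.66	0	0.67	Alter by SPiCE	No	98.41	-3.87	1.00
c.714A>G	p.Gln238=	10	0	0	0	0.02	0.01	Alter by creating a new splice site + Alter ESR	No	47.89	-0.19
c.773A>C	p.Gln258Pro	10	0.000002478	0.01	0.04	0.09	0.05	Alter by SPiCE	No	98.41	-0.45	0.88
c.775-16T>A		11	0.0000006433	0.81	0.35	0	0.05	Alter by MES (Poly TC)	No	98.41	-2.56
c.1006+6T>C		12	0	0	0.45	0	0.57	Alter by SPiCE	No	96.71	-1.04
c.899T>G	p.Val300Gly	12	0.00004151	0.5	0.01	0.07	0	NTR	No	9.76	0.37	0.95
c.1007-167A>T		13	0	0.47	0	0.66	0.01	Alter by creating de Novo Exon	No	2.66	-0.17
c.1007G>A	p.Arg336Lys	13	0	0.09	0.15	0	0.03	Alter by SPiCE	No	43.04	-0.95	0.79
c.1007G>C	p.Arg336Thr	13	0	0.11	0.24	0	0.04	Alter by SPiCE	No	30.67	-0.79	0.98
c.1060C>T	p.Gln354Ter	13	0	0.02	0.06	0	0.02	Alter by creating a new splice site + Alter ESR	No	26.62	-0.19
c.1188+8T>A		13	0.000001239	0	0.01	0.15	0	Alter by creating a new splice site	No	30.67	-0.57
c.1188+8T>C		13	0	0	0	0.02	0	Alter by creating a new splice site	No	13.87	-0.06
c.1189-8T>A		14	0	0	0.21	0	0.06	Alter by SPiCE	No	43.04	-0.70
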