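variant	protein	exon	effect	delta_psi_abs	wt_baseline_psi	criteria_before	criteria_after_published	class_before_published	class_after_published	analyzed	note
c.158G>A	p.Arg53Gln	3	missense	-6.8		PM3;PP3;PM2;PM5;PP2;PP5	-	Likely pathogenic	-	yes
c.174A>T	p.Arg58Ser	3	missense	-94.9		PM3;PP3;PM2;PM5;PP2;PP5	PM3;PP3;PM2;PP5;PS3	Likely pathogenic	Pathogenic	yes
c.177-35T>G		4	intronic	-1.0		PM2;BP7	PM2;BP7;BS3	VUS	Likely benign	yes
c.342+3A>C		5	intronic	-90.5		PM3;PP3;PM2;PP5	PM3;PP3;PM2;PP5;PS3	Likely pathogenic	Pathogenic	yes
c.342+9G>T		5	intronic	0.6		PM2;BP4;BP6	PM2;BP4;BP6;BS3	Likely benign	Likely benign	yes
c.343-6T>A		6	intronic	-5.3		PM2;BP6	PM2;BP6;BS3	VUS	Likely benign	yes
c.343G>C	p.Gly115Arg	6	missense	-39.0		PM3;PP3;PM2;PM1;PP2;PP5	-	Likely pathogenic	-	yes
c.433A>T	p.Arg145Ter	6	nonsense	-1.2		PVS1;PM2;PM3;PP5	-	Pathogenic	-	yes
c.455G>C	p.Gly152Ala	7	missense	7.8		PP3;PM2;PM1;PM5;PP2	-	Likely pathogenic	-	yes
c.469+5G>A		7	intronic	-88.0		PP3;PM2;PM3;PP5	PP3;PM2;PM3;PP5;PS3	Likely pathogenic	Pathogenic	yes
c.469+6T>C		7	intronic	-65.6		PP3;PM2;PM3;PP5	PP3;PM2;PM3;PP5;PS3	Likely pathogenic	Pathogenic	yes
c.469G>T	p.Val157Phe	7	missense	-84.5		PP3;PM2;PP2;PM3;PP5	PP3;PM2;PM3;PP5;PS3	Likely pathogenic	Pathogenic	yes
c.549G>T	p.Gln183His	8	missense	-48.1		PP3;PM2;PM5;PP2	-	Likely pathogenic	-	no	construct carried a cloning artifact; excluded from the analyzed set
c.612T>C	p.Tyr204=	9	synonymous	47.2	22.7	PM2;BP7;BP6	PM2;BP7;BP6;BS3	Likely benign	Likely benign	yes
c.624T>C	p.Phe208=	9	synonymous	52.6	22.7	PM2;BS2;BP7;BP6	PM2;BS2;BP7;BP6;BS3	Likely benign	Benign	yes
c.649G>T	p.Gly217Trp	9	missense	-22.7	22.7	PP3;PM2;PP2;PM3;PP5	-	Likely pathogenic	-	yes
c.714A>G	p.Gln238=	10	synonymous	12.1		PM2;BP7;BP6	PM2;BP7;BP6;BS3	Likely benign	Likely benign	yes
c.773A>C	p.Gln258Pro	10	missense	-19.6		PM2;PM1;PP3;PP2;PM3;PP5	-	Likely pathogenic	-	yes
c.775-16T>A		11	intronic	-94.9		PM2;PM3;PP5;PP3	PM2;PM3;PP5;PP3;PS3	Likely pathogenic	Pathogenic	yes
c.1006+6T>C		12	intronic	-54.7		PP3;PM2;PP5	PP3;PM2;PP5;PS3	VUS	Likely pathogenic	yes
c.899T>G	p.Val300Gly	12	missense	5.3		PM3;PP3;PM2;PM5;PP2;PP5	-	Likely pathogenic	-	yes
c.1007-167A>T		13	intronic	-72.5		PM2;PM3;PP3;PP4	PM2;PM3;PP3;PP4;PS3	Likely pathogenic	Pathogenic	yes
c.1007G>A	p.Arg336Lys	13	missense	-28.1		PM2;PM1;PP3;PM5;PP2;PM3;PP5	-	Likely pathogenic	-	yes
c.1007G>C	p.Arg336Thr	13	missense	-55.6		PP3;PM2;PM1;PM5;PP2;PM3;PP5	PP3;PM2;PM3;PP5;PS3	Likely pathogenic	Pathogenic	yes
c.1060C>T	p.Gln354Ter	13	nonsense	-21.0		PVS1;PM2;PM3;PP5	-	Pathogenic	-	yes
c.1188+8T>A		13	intronic	7.7		PM2;PM3;PP5	PM2;PM3;PP5;BS3	VUS	VUS	yes
c.1188+8T>C		13	intronic	9.5		PM2;BP4;BP6	PM2;BP4;BP6;BS3	Likely benign	Likely benign	yes
c.1189-8T>A		14	intronic	0		PM2;BP6	PM2;BP6;BS3	VUS	Likely benign	yes
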