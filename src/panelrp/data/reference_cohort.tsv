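family	gene	gene_inheritance	ad_hotspot	index_sex	allele1_cdna	allele1_protein	allele1_consequence	allele1_method	allele1_known	allele2_cdna	allele2_protein	allele2_consequence	allele2_method	allele2_known	segregation
RP-1147	CNGA1	AR		U	c.94C>T	p.Arg32*	nonsense	aC	1	c.830G>A	p.Arg277Gln	missense	H	0	Yes
RP-2066	PDE6A	AR		U	c.1705C>A	p.Gln569Lys	missense	aC	1	c.1620+1G>T		canonical_splice	H	0	NA
RP-2114	RDH12	AR		U	c.278T>C	p.Leu93Pro	missense	aC	1	c.210-211insC	p.Arg71Glnfs*12	frameshift	H	0	NA
RP-1319	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.920-923dupGCCA	p.His308Glnfs*16	frameshift	H	1	NA
RP-1412	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.1214delA	p.Asn405Ilefs*3	frameshift	H	1	Yes
RP-1646	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.12575G>A	p.Arg4192His	missense	H	1	Yes
RP-1695	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.9799T>C	p.Cys3267Arg	missense	H	1	NA
RP-1735	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.12153-12175delAATTTTAAGCCCTTGGACTCTGA	p.Glu4051Aspfs*40	frameshift	H	0	NA
RP-1802	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.920-923dupGCCA	p.His308Glnfs*16	frameshift	H	1	Yes
RP-1976	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.8254G>A	p.Gly2752Arg	missense	H	1	NA
RP-1979	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.1606T>C	p.Cys536Arg	missense	H	1	Yes
RP-2112	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	Deletion Ex.45-49		cnv_deletion	H	1	NA
RP-2113	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	aC	1	c.5462A>G	p.Lys1821Arg	missense	H	0	Yes
RP-1543	ABCA4	AR		U	c.4234C>T	p.Gln1412*	nonsense	H	1	c.5917delG	p.Val1973*	frameshift	H	1	NA
RP-1056	CERKL	AR		U	c.847C>T	p.Arg283*	nonsense	H	1	c.664C>T	p.Gln222*	nonsense	H	0	Yes
RP-1998	CNGB1	AR		U	c.2957A>T	p.Asn986Ile	missense	H	1	c.2957A>T	p.Asn986Ile	missense	H	1	Yes
RP-1706	EYS	AR		U	c.2826-2827delAT	p.Val944Glyfs*9	frameshift	H	0	Deletion Ex.19		cnv_deletion	H	0	Yes
RP-1929	EYS	AR		U	c.9142dupA	p.Arg3048Lysfs*9	frameshift	H	0	Deletion Ex.13-14		cnv_deletion	H	1	NA
RP-1142	GUCY2D	AR		U	c.1762C>T	p.Arg588Trp	missense	H	1	c.1762C>T	p.Arg588Trp	missense	H	1	Yes
RP-0372	PDE6A	AR		U	c.1957C>T	p.Arg653*	nonsense	H	0	c.1957C>T	p.Arg653*	nonsense	H	0	Yes
RP-0040	PRCD	AR		U	c.74+1G>A		canonical_splice	H	0	c.74+1G>A		canonical_splice	H	0	Yes
RP-1772	RP1	AR,AD	500-1053	U	c.2431delA	p.Ser812Valfs*36	frameshift	H	0						Yes
RP-1988	RP1	AR,AD	500-1053	U	c.400-401insGC	p.His136Argfs*8	frameshift	H	0	c.400-401insGC	p.His136Argfs*8	frameshift	H	0	Yes
RP-1201	RP2	XL		M	c.708C>G	p.Cys236Trp	missense	H	0						Yes
RP-0338	USH2A	AR		U	c.9433C>T	p.Leu3145Phe	missense	H	0	c.9433C>T	p.Leu3145Phe	missense	H	0	Yes
RP-0344	USH2A	AR		U	c.8693A>C	p.Tyr2898Ser	missense	H	1	c.10008C>A	p.Cys3336*	nonsense	H	0	Yes
RP-0456	USH2A	AR		U	c.2276G>T	p.Cys759Phe	missense	H	1	c.10709G>T	p.Cys3570Phe	missense	H	0	NA
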