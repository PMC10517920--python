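gene	chromosome	start	end	transcript	exon	nucleotide	amino_acid	disease	twb_af	max_external_af	printed_class	criteria
HYAL1	3	50302735	50302735	NM_153281	exon4	c.221dupT	p.Y75Lfs*2	Mucopolysaccharidosis type IX	0.0005	0.0006	Likely pathogenic	PS1;PM3
HPS3	3	149172202	149172202	NM_032383	exon17	c.C2995T	p.R999X	Hermansky-Pudlak syndrome 3	0.0005	0.0005	Pathogenic	PS1;PM3;PP4
MANBA	4	102722993	102722993	NM_005908	exon4	c.427delC	p.R143Vfs*73	Beta-mannosidosis	0.0005	0.0005	Likely pathogenic	PS1;PM3
MFSD8	4	127965131	127965131	NM_152778	exon2	c.G3C	p.M1?	Neuronal ceroid lipofuscinosis 7	0.0005	0.0005	Likely pathogenic	PS1;PM3
GUSB	7	65970302	65970302	NM_000181	exon9	c.1455dupT	p.N486*	Mucopolysaccharidosis type VII	0.0005	0.0005	Likely pathogenic	PS1;PM3
ASAH1	8	18063213	18063213	NM_177924	exon7	c.A475T	p.R159X	Farber lipogranulomatosis	0.0005	0.0005	Pathogenic	PS1;PM3;PP4
HGSNAT	8	43140604	43140604	NM_152419	exon1	c.108_109insCCGCCACGAGGTGAGTGCACACCTCCTA	p.D40Gfs*30	Mucopolysaccharidosis type IIIC	0.0005	0.0005	Likely pathogenic	PS1;PM3
GNE	9	36246215	36246215	NM_001128227	exon3	c.524dupA	p.D175Efs*30	Sialuria	0.0005	0.0005	Likely pathogenic	PS1;PM3
HPS6	10	102067113	102067114	NM_024747	exon1	c.1639_1640del	p.L548Rfs*18	Hermansky-Pudlak syndrome 6	0.0005	0.0005	Likely pathogenic	PS1;PM3
PNPLA2	11	821684	821684	NM_020376	exon3	c.G244A	p.G82S	Neutral lipid storage disease	0.0005	0.0005	Likely pathogenic	PS1;PM3
PNPLA2	11	824737	824737	NM_020376	exon10	c.1390delC	p.A465Pfs*24	Neutral lipid storage disease	0.0005	0.0005	Likely pathogenic	PS1;PM3
SMPD1	11	6391633	6391640	NM_000543	exon2	c.568_575del	p.P194Rfs*12	Niemann-Pick disease type A/B	0.0035	0.0035	Likely pathogenic	PS1;PM3
HPS5	11	18291846	18291846	NM_181507	exon16	c.C2036A	p.S679X	Hermansky-Pudlak syndrome 5	0.0015	0.0015	Pathogenic	PS1;PM3;PP4
CTSF	11	66566045	66566045	NM_003793	exon6	c.844delG	p.A282Lfs*64	Neuronal ceroid lipofuscinosis 13	0.0005	0.0005	Likely pathogenic	PS1;PM3
CTSC	11	88296248	88296248	NM_001814	exon6	c.C774A	p.C258X	Periodontitis 1	0.0005	0.0005	Pathogenic	PS1;PM3;PP4
HEXA	15	72350530	72350530	NM_000520	exon7	c.T793C	p.S265P	GM2-gangliosidosis/Tay-Sachs disease	0.0005	0.0005	Likely pathogenic	PS1;PM3
GNPTG	16	1363060	1363060	NM_032520	exon11	c.887delG	p.G297Vfs*37	Mucolipidosis III gamma	0.0005	0.0005	Likely pathogenic	PS1;PM3
GALNS	16	88832003	88832003	NM_000512	exon9	c.G997A	p.G333S	Mucopolysaccharidosis type IVA	0.0005	0.0005	Likely pathogenic	PS1;PM3
GALNS	16	88856761	88856761	NM_000512	exon1	c.C117G	p.D39E	Mucopolysaccharidosis type IVA	0.0005	0.0005	Likely pathogenic	PS1;PM3
NAGLU	17	42544009	42544009	NM_000263	exon6	c.2003delC	p.N669Tfs*138	Mucopolysaccharidosis type IIIB	0.0005	0.0005	Likely pathogenic	PS1;PM3
CTSA	20	45898426	45898426	NM_000308	exon15	c.1420dupT	p.L475Pfs*17	Galactosialidosis	0.0005	0.0005	Likely pathogenic	PS1;PM3
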