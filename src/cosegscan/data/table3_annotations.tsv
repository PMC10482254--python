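gene	effect	evs	gonl	exac	polyphen_score	polyphen_class	sift_score	sift_class	conservation_nt	conservation_aa
GRINA	NS	1/13005	0	0/121000	1	probably damaging	0	deleterious	highly	highly
OR1J1	NS	0	0	1/120930	0.001	benign	0.56	tolerated	weakly	highly
RABEPK	NS	11/12995	2/996	36/120704	1	probably damaging	0	deleterious	highly	highly
DEPDC7	NS	0	0	0/120000	0.896	possibly damaging	0.07	tolerated	moderately	moderately
MAML2	NS	1/12217	0	50/119130	0.998	probably damaging	0.06	tolerated	moderately	highly
OR8D4	NS	6/12996	1/996	102/121352	0	benign	0	deleterious	weakly	weakly
DDX25	NS	1/12537	1/996	3/76840	0	benign	0.49	tolerated	weakly	highly
CACNA2D4	SS	0	0	3/120548	undef	undef	undef	undef	undef	undef
TMED3	NS	0	0	0/121000	0.773	possibly damaging	0.06	tolerated	moderately	highly
MYO15A	NS	17/12365	4/996	199/119810	0.999	probably damaging	undef	undef	weakly	highly
STAU1	NS	3/13003	0	16/121402	0.911	possibly damaging	0.33	tolerated	weakly	highly
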