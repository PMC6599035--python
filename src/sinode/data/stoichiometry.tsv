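protein	subunits	note
Hcn4	4	tetramer; fixed by the analysis convention
Hcn1	4	tetramer
Hcn2	4	tetramer
Cacna1c	1	Cav1.2 alpha subunit; monomeric alpha, fixed by convention
Cacna1d	1	Cav1.3 alpha subunit
Cacna1g	1	Cav3.1 alpha subunit
Cacna1h	1	Cav3.2 alpha subunit
Kcnh2	4	ERG / Kv11.1 tetramer
Kcnq1	4	Kv7.1 tetramer
Kcna5	4	Kv1.5 tetramer
Kcnd3	4	Kv4.3 tetramer
Kcnj3	4	Kir3.1 tetramer
Kcnj5	4	Kir3.4 tetramer
Kcnj2	4	Kir2.1 tetramer
Kcnk3	2	TASK-1 two-pore dimer
Kcnk1	2	TWIK-1 two-pore dimer
Scn5a	1	Nav1.5 alpha subunit
Ryr2	4	ryanodine receptor tetramer
Atp2a2	1	Serca2 monomer
Slc8a1	1	Ncx1 monomer
Gja1	6	connexin-43 hemichannel
Gja5	6	connexin-40 hemichannel
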