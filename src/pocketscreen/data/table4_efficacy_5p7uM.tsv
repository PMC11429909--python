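cell_line	Dxr2-017	FolC2-001	FolC1-020	TYLT-072
HT116	0.69	0.85	0.88	0.83
HT29	0.03	1.13	0.69	1.22
MCF-7	0.39	0.65	0.08	0.94
MDAMB231	0.05	0.81	0.96	0.95
H226	0.12	0.56	0.96	0.26
A549	1.26	0.99	0.84	0.99
PC3-M	0.41	0.96	0.76	1.02
LNCaP	0.49	0.82	-	-
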