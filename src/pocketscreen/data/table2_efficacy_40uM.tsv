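cell_line	Dxr2-017	Dxr2-055	Dxr2-069	FolC2-001	FolC2-005	FolC2-044	FolC1-042	FolC1-020	Dxr1-021	TYLT-072
HT116	0.08	0.63	0.93	0.60	0.70	0.03	0.51	0.23	0.95	1.18
HT29	0.00	0.00	0.01	0.79	0.06	0.00	0.10	0.12	0.59	2.05
MCF-7	0.02	0.04	0.03	0.43	0.33	0.01	0.64	0.01	0.81	0.98
MDAMB231	0.00	0.05	0.59	0.28	0.78	0.16	0.65	0.65	0.62	0.97
H226	0.02	0.10	0.03	0.00	0.11	0.00	0.01	0.26	1.26	0.14
A549	0.07	0.96	0.15	0.53	0.69	0.15	0.96	0.89	0.72	1.17
PC3-M	0.00	0.00	0.00	0.41	0.00	0.00	0.18	0.13	0.38	0.99
LNCaP	0.05	0.40	-	0.34	0.28	-	-	-	-	-
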