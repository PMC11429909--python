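compound	day8_pct_control	day14_pct_control
Dxr2-001	109	93
Dxr2-017	70	57
Dxr2-054	79	112
Dxr2-055	99	115
Dxr2-069	108	75
FolC2-001	108	87
FolC2-005	105	101
FolC2-025	93	109
FolC2-044	96	73
FolC2-048	87	120
FolC1-020	107	97
FolC1-031	80	85
FolC1-042	105	102
FolC1-087	107	94
FolC1-100	98	96
Dxr1-005	106	90
Dxr1-021	101	80
Dxr1-026	100	128
Dxr1-070	96	97
Dxr1-083	97	93
TYLT-001	117	103
TYLT-003	97	94
TYLT-051	84	103
TYLT-072	88	104
TYLT-088	101	112
FabG-033	102	94
FabG-035	113	105
FabG-036	106	100
FabG-045	97	103
FabG-073	97	92
PRT-009	111	101
PRT-031	106	97
PRT-044	101	93
PRT-051	93	119
PRT-P89	111	93
EPSP-023	94	114
EPSP-044	98	98
EPSP-065	99	98
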