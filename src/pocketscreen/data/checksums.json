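{
  "table1_bone_marrow.tsv": "5f9dbc129a00fea232c6a3bad216374aa25916f19de658e877227276689ef4eb",
  "table2_efficacy_40uM.tsv": "1480858fe9e6f4cb5750059569dcdbc184c5b87a9dd6ceecdb4a864992780cf7",
  "table4_efficacy_5p7uM.tsv": "64bc3fb1c84d2e316803453cebe16d32b9a63314f34c5159b756470dabb8c4c6"
}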