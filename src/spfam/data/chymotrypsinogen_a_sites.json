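{
  "description": "Annotated positions in bovine chymotrypsinogen A, 1-based zymogen numbering (residue 1 = Cys1). S1-pocket positions 189/216/226 define trypsin vs chymotrypsin substrate specificity.",
  "id": "CTRA_BOVIN",
  "catalytic": {"his": 57, "asp": 102, "ser": 195},
  "s1_pocket": {"res189": 189, "res216": 216, "res226": 226},
  "activation": {"p1": 15, "motif_start": 16}
}
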