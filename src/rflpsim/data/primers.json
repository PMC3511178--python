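{
  "comment": "Published six-primer panel for the multiplex assay covering MTHFR 677 C>T (rs1801133), eNOS +894 G>T (rs1799983) and eNOS -786 T>C (rs2070744).",
  "panel": [
    {"name": "677F", "sequence": "CTCGCCTTGAACAGGTGGAG", "assay": "rs1801133", "role": "forward"},
    {"name": "677R", "sequence": "CTGGATGGGAAAGATCCCGG", "assay": "rs1801133", "role": "reverse"},
    {"name": "894F", "sequence": "GTCCCTGAGGAGGGCATGAG", "assay": "rs1799983", "role": "forward"},
    {"name": "894R", "sequence": "TCCAGCAGCATGTTGGACAC", "assay": "rs1799983", "role": "reverse"},
    {"name": "786F", "sequence": "GCAGGTCAGCAGAGAGACTA", "assay": "rs2070744", "role": "forward"},
    {"name": "786R", "sequence": "GACACAGAACTACAAACCCC", "assay": "rs2070744", "role": "reverse"}
  ]
}
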