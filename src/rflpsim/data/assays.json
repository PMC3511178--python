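{
  "comment": "Machine form of the published genotype -> band-size table. genotype_bands is what the caller uses; every cut-allele row conserves the amplicon length. published_bands preserves the printed table verbatim where it differs: the BanII heterozygote/homozygote rows print 139 bp for the small cut fragment, which cannot arise from a single cut of a 371 bp amplicon (223 + 139 = 362 != 371); the length-conserving 148 bp is used for calling and the printed value is carried here with a flag.",
  "assays": [
    {
      "snp_id": "rs1801133",
      "locus_label": "MTHFR 677 C > T",
      "forward_primer": "677F",
      "reverse_primer": "677R",
      "amplicon_length": 248,
      "enzyme": "HinfI",
      "alleles": ["C", "T"],
      "cut_allele": "T",
      "genotype_bands": {
        "CC": [248],
        "CT": [248, 130, 118],
        "TT": [130, 118]
      }
    },
    {
      "snp_id": "rs2070744",
      "locus_label": "eNOS -786 T > C",
      "forward_primer": "786F",
      "reverse_primer": "786R",
      "amplicon_length": 178,
      "enzyme": "MspI",
      "alleles": ["T", "C"],
      "cut_allele": "T",
      "genotype_bands": {
        "CC": [178],
        "TC": [178, 137, 41],
        "TT": [137, 41]
      }
    },
    {
      "snp_id": "rs1799983",
      "locus_label": "eNOS +894 G > T",
      "forward_primer": "894F",
      "reverse_primer": "894R",
      "amplicon_length": 371,
      "enzyme": "BanII",
      "alleles": ["G", "T"],
      "cut_allele": "T",
      "genotype_bands": {
        "GG": [371],
        "GT": [371, 223, 148],
        "TT": [223, 148]
      },
      "published_bands": {
        "GG": [371],
        "GT": [371, 223, 139],
        "TT": [223, 139]
      },
      "published_note": "printed small fragment 139 bp is inconsistent with the 371 bp amplicon (223 + 139 != 371); 148 bp conserves length and is used for calling"
    }
  ]
}
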