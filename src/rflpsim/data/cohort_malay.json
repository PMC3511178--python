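{
  "comment": "Genotype frequencies observed in 114 healthy Malaysian Malay subjects (published cohort table). Genotype order matches the assay allele order: (hom_first_allele, het, hom_second_allele). Counts are not printed in the source; reconstructed_counts = round(freq * n) are provided for demonstration and flagged as reconstructed.",
  "n": 114,
  "cohorts": [
    {
      "snp_id": "rs1801133",
      "genotypes": ["CC", "CT", "TT"],
      "frequencies": [0.79, 0.20, 0.01],
      "reconstructed_counts": [90, 23, 1]
    },
    {
      "snp_id": "rs1799983",
      "genotypes": ["GG", "GT", "TT"],
      "frequencies": [0.32, 0.52, 0.16],
      "reconstructed_counts": [36, 59, 18]
    },
    {
      "snp_id": "rs2070744",
      "genotypes": ["TT", "TC", "CC"],
      "frequencies": [0.80, 0.15, 0.05],
      "reconstructed_counts": [91, 17, 6]
    }
  ]
}
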