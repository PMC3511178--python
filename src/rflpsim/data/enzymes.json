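{
  "comment": "Restriction enzymes used by the assay. cut_offset is the distance in bases from the 5' end of the recognition site to the top-strand cleavage point (REBASE convention): HinfI G^ANTC, MspI C^CGG, BanII GRGCY^C.",
  "enzymes": [
    {"name": "HinfI", "recognition": "GANTC", "cut_offset": 1},
    {"name": "MspI", "recognition": "CCGG", "cut_offset": 1},
    {"name": "BanII", "recognition": "GRGCYC", "cut_offset": 5}
  ]
}
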