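# rflpsim

In-silico multiplex PCR-RFLP genotyping for three cardiovascular risk
variants: *MTHFR* 677 C>T (rs1801133), *eNOS* +894 G>T (rs1799983) and
*eNOS* −786 T>C (rs2070744).

PCR-RFLP genotyping reads a single-nucleotide polymorphism off a gel: the
variant base creates or destroys a restriction enzyme's recognition site
inside a PCR product, so the fragment sizes after digestion identify the
genotype. A heterozygote shows the union of both alleles' fragments in one
lane. `rflpsim` models the whole desk side of such an assay:

- **Virtual PCR** — locate primer binding sites (with a mismatch budget and
  a mismatch-free 3′ clamp window) and enumerate predicted amplicons for a
  multiplex panel, including unintended cross-pair products and a 3′
  primer-dimer heuristic.
- **Virtual digestion** — scan IUPAC-degenerate recognition sites
  (HinfI `GANTC`, MspI `CCGG`, BanII `GRGCYC`), cut at the top-strand
  offset, and report fragment sizes; diploid lanes are the union of both
  alleles' fragments.
- **Genotype calling** — match observed band sizes against the assay's
  expected-band table under a gel model (size tolerance, detection limit),
  with explicit `ambiguous` / `no_call` outcomes, and partition multiplexed
  lanes among assays.
- **Primer thermodynamics** — Wallace rule `Tm = 2(A+T) + 4(G+C)`,
  nearest-neighbor `Tm = ΔH/(ΔS + R ln(c/4)) + 16.6 log₁₀[K⁺] − 273.15`
  (unified 1998 ΔH/ΔS table, injectable), product
  `Tm = 81.5 + 0.41(%GC) + 16.6 log₁₀[K⁺] − 675/L`, annealing
  `Ta = 0.3 Tm(primer) + 0.7 Tm(product) − 14.9`, and the 1 kb/min
  extension-time rule.
- **Cohort statistics** — gene-counting allele frequencies
  `p = f(hom) + f(het)/2`, Hardy-Weinberg expectations `(p², 2pq, q²)` and a
  1-df chi-square goodness-of-fit test.
- **Synthetic fixtures** — seedable diploid templates whose amplicon and
  cut geometry realize the published fragment sizes exactly (248 → 130+118;
  178 → 137+41; 371 → 223+148), plus Hardy-Weinberg cohort simulation.

## Worked example

Simulate a heterozygous MTHFR 677 sample and read its lane:

```text
$ rflpsim simulate rs1801133 CT --seed 1
# MTHFR 677 C > T (rs1801133), genotype CT, seed 1
amplicon	677F/677R	60-308	248 bp
bands	HinfI	248, 130, 118
```

The 248 bp product is the undigested C allele; the T allele completes the
HinfI site `GANTC`, which cuts the same product into 130 + 118 bp — three
bands in one lane is the heterozygote signature. Calling band lists back to
genotypes:

```text
$ printf 'lane2\t371, 248, 178, 130, 118\n' > lanes.tsv
$ rflpsim call lanes.tsv
lane	snp_id	genotype	matched	unexplained	flags
lane2	rs1801133	CT	118,130,248
lane2	rs2070744	CC	178
lane2	rs1799983	GG	371
```

Cohort statistics for the packaged healthy-cohort rows (n = 114):

```text
$ rflpsim popstats --published
snp_id	n	...	allele_1	allele_1_freq	allele_2	allele_2_freq
rs1801133	114	...	C	0.89	T	0.11
rs1799983	114	...	G	0.58	T	0.42
rs2070744	114	...	T	0.88	C	0.13
```

Here `allele_1_freq` is the gene-counting estimate: for rs1801133,
0.79 + 0.20/2 = 0.89 for the C allele. The −786 T allele is exactly 0.875
at full precision and is reported half-up as 0.88.

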