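# Methods

## Model of the assay

`rflpsim` treats a PCR-RFLP genotyping assay as a deterministic pipeline on
DNA strings. A template is an IUPAC nucleotide sequence with 0-based,
half-open, plus-strand coordinates. Virtual PCR enumerates products from
primer binding sites; virtual digestion cuts products at degenerate
recognition sites; a genotype is called by matching the resulting band
sizes against a per-SNP expected-band table. There is no kinetic or yield
model: amplification and digestion are complete and exact, which matches
how such assays are designed and interpreted (cycling conditions are
carried as metadata only).

### Binding sites and amplicons

A primer binds the plus strand where its sequence matches left-to-right and
the minus strand where its reverse complement matches. Two parameters
govern a hit: `max_mismatches` (default 0 — the assay's primers are
exact-match by design) and `clamp_len` (default 8), the 3′-terminal window
that must be mismatch-free because the polymerase extends from the 3′ end
and mismatches there abolish priming. Every (plus-strand site, downstream
minus-strand site) pair with a 5′-to-5′ span of at most `max_len`
(default 2000 bp) yields a product; self-pairings are included. Product
length runs from the forward primer's 5′ base through the reverse primer's
5′ base inclusive — both primers are part of the product, which is how gel
product sizes (248, 371, 178 bp here) are conventionally reported. The
multiplex report additionally flags unintended cross-pair products and
primer pairs whose 3′-terminal trinucleotides are mutually complementary
(a standard primer-dimer heuristic).

Degenerate template bases are handled conservatively everywhere: a
template base matches a pattern position only if its IUPAC set is a subset
of the pattern's set, so a site that may not exist is never reported.

### Digestion and band sets

An enzyme is a degenerate recognition pattern plus a top-strand cut offset
(REBASE chemistry: HinfI G^ANTC → 1, MspI C^CGG → 1, BanII GRGCY^C → 5;
shipped as editable JSON). Cut positions are `site.start + cut_offset` for
every hit on either strand, deduplicated; fragments are the inter-cut
intervals and always sum to the input length (asserted on every digest).
Fragment sizing uses top-strand cut positions only: gels cannot resolve
sticky-end overhang asymmetry. A consequence worth stating is that
digesting the reverse complement shifts every boundary by the overhang
asymmetry `m − 2·cut_offset` (3 bp for HinfI, 2 for MspI, 4 for BanII);
internal fragments are identical and only the two terminal fragments trade
the overhang. The tests assert this exact form rather than naive fragment
equality. Partial digestion, star activity and methylation sensitivity are
not modeled. A diploid lane is the union of both alleles' distinct
fragment lengths (equal-length fragments co-migrate).

### Genotype calling

Each assay's three genotypes map to expected band sets (packaged JSON
mirroring the published table). The gel model has two tunables:

- `size_tolerance` — absolute matching tolerance, default 5 bp.
  High-resolution 5% agarose discriminates roughly 10 bp in the 40–400 bp
  range, so ±5 bp is a conservative reading error.
- `min_detectable` — smallest visible band, default 30 bp (the size
  standard used for such gels starts at 25 bp). Expected bands below this
  are dropped before matching and surfaced as flags.

A genotype matches when the remaining expected bands and the observed bands
pair one-to-one within tolerance, with no observed band left unexplained.
One match → that call; none → `no_call`; several → `ambiguous` with
candidates listed. Multiplexed lanes are first partitioned by
nearest-expected-size; a band within tolerance of several assays is flagged
on all of them, never silently assigned. Calls are invariant to band order.

Two published quirks are carried as data, not code:

- The BanII (eNOS +894) rows print cut fragments "223, 139", but
  223 + 139 ≠ 371: no single cut of a 371 bp product can produce them. The
  packaged assay stores the length-conserving {223, 148} for calling and
  carries the printed row verbatim in `published_bands` with a note; the
  139 value is never realized.
- The −786 orientation is implemented exactly as printed (the T allele
  carries the MspI site; CC is the uncut "wild type"), although other
  literature orients this SNP the other way.
- The published worked gel lane {371, 248, 178, 130, 118} is, under the
  band table, a clean MTHFR CT call (248 + 130 + 118); the accompanying
  caption calls it TT, implicitly treating 248 bp as undigested carryover.
  The caller reports CT and leaves that reinterpretation to the analyst.

### Thermodynamics

`tm_wallace` is the exact integer rule 2(A+T) + 4(G+C). `tm_nearest_neighbor`
evaluates Tm(°C) = ΔH/(ΔS + R·ln(c/4)) + salt − 273.15 with ΔH, ΔS summed
from the unified 1998 dinucleotide table (packaged JSON, injectable via
`ThermoParams.nn_table`); `c` is total strand concentration (default
0.25 µM, a typical PCR value; the c/4 form assumes non-self-complementary
duplexes, which holds for all packaged primers) and R = 1.987 cal K⁻¹ mol⁻¹.
Two monovalent-salt corrections are offered:

- `"schildkraut"` (default): the additive `16.6·log₁₀([K⁺] in M)` term.
- `"owczarzy"`: the reciprocal-Kelvin, GC-dependent correction used by
  common primer-design software.

At 50 mM K⁺ the additive term subtracts 21.6 °C, and the resulting Tm sits
a uniform ~7–8 °C below the values such software prints for the packaged
panel; the Owczarzy form reproduces those printed values within ~1.5 °C.
Both behaviors are asserted in the tests, and the printed panel Tm values
are treated as a soft ±3 °C window around the Owczarzy computation, never
as exact targets (the generating parameter set is not published). No
divalent/Mg²⁺ correction or mismatch thermodynamics are modeled. Units:
molar for the log terms (millimolar inputs are converted), °C outputs.

The product Tm, annealing temperature (Ta = 0.3 Tm_primer + 0.7 Tm_product
− 14.9, using the lower of the two primers' NN Tm as the limiting primer)
and the 1000 bases/min extension rule are direct formula evaluations. The
assay's real-genome annealing temperatures cannot be recomputed without the
genomic amplicon GC%, which this package does not ship.

### Cohort statistics

Allele frequencies come from gene counting, p = f(hom) + f(het)/2 with
q = 1 − p (rows given as rounded frequencies are renormalized so p + q = 1
exactly). Hardy-Weinberg expectations are (p², 2pq, q²); the goodness-of-fit
statistic is Σ(obs − n·exp)²/(n·exp) over the three genotype classes with
the allele frequency estimated from the data, 1 degree of freedom, p-value
from the χ² distribution (scipy), no continuity correction. Classes with
zero expectation (monomorphic data) are skipped and flagged degenerate.
Reporting rounds half-up to 2 decimals at the output layer only; internals
are full precision. The packaged −786 row therefore reports T = 0.88 /
C = 0.13 from the exact 0.875/0.125, preferring internal consistency over
matching one inconsistently rounded published cell (which prints 0.87 next
to 0.13). The packaged cohort ships genotype *frequencies* (n = 114);
integer counts are not published, so `reconstructed_counts = round(f·114)`
are provided for exercising the χ² path and flagged as approximate (the
+894 row sums to 113).

## Synthetic fixtures: what they emulate and what they do not

`fixtures.make_template` builds, per assay, a diploid template: published
primer embedded verbatim at each end of an amplicon of the published length,
the enzyme's recognition site planted so the variant base toggles it and the
top-strand cut lands at the published fragment boundary
(248 → cut 130; 178 → cut 137; 371 → cut 223), and random background
elsewhere, flanked by 60 bp of random sequence. Background draws are
rejected and resampled whenever they would create an extra panel binding
site anywhere on the template or an extra recognition site inside the
amplicon, so virtual PCR yields exactly one product per template and
digestion yields exactly the planted fragments — for any seed. Sequences
are deterministic per (assay, seed) via a named generator whose stream is
derived from the seed and the SNP id; FASTA headers record snp, genotype,
allele and seed.

Allele lettering: rs1801133 and rs1799983 place the dbSNP allele letter
literally on the amplicon plus strand (GACTC/GACCC; GGGCTC/GGGCGC). For
rs2070744 no strand assignment puts a literal T inside CCGG, so the
amplicon is treated as the opposite strand to the allele naming: the
site-carrying "T" allele holds C (CCGG, cut) and the "C" allele holds T
(CTGG, uncut), realizing the printed orientation.

These fixtures are geometric stand-ins, not genomics: they share none of
the real loci's flanking sequence, repeat structure, GC landscape or
off-target binding opportunities. Passing tests therefore demonstrate that
the *engine* (scanning, pairing, cutting, calling, counting) is correct on
sequences with the published geometry — not that the published primers are
specific against the human genome, which would require the real assemblies
and is out of scope.

Cohort simulation draws n independent genotypes from (p², 2pq, q²). It
emulates random mating and independent sampling only — no inbreeding,
population structure, genotyping error or missingness.

## Numerical and testing choices

- Monte-Carlo sizes: the χ² type-I calibration and the allele-frequency
  recovery checks use 1000 replicates of n = 114 cohorts (seeded), with a
  3σ binomial band on the rejection rate and a 2-SE band on the mean
  estimate. Calibration is run at p = 0.5 where the three expected class
  counts are large; at p ≈ 0.89 the rare-homozygote class expectation is
  ~1.4 and the χ² approximation is known to be rough.
- Oracle equality checks (motif scan, binding sites, digestion, amplicon
  pairing) compare against brute-force scanners written independently in
  the tests; the nearest-neighbor Tm is additionally cross-checked against
  an independent implementation (Biopython `Tm_NN`) under identical
  parameter conventions.
- Band matching pairs sorted expected against sorted observed lists, exact
  whenever the tolerance is below half the spacing of adjacent expected
  sizes (the closest pair in the packaged tables is 130 vs 137 bp, so the
  default ±5 bp qualifies within one assay; across assays the 133 bp
  midpoint case is flagged as shared).
- Degenerate inputs: empty lanes give `no_call`; a detection limit that
  erases all distinguishing bands gives `ambiguous`; fragment conservation
  is asserted on every digest; cut positions falling on a sequence boundary
  are no-ops.

## Known limitations

- No real genomic context (see fixtures above); BLAST-style specificity
  checking is out of scope.
- No partial digestion, enzyme kinetics, buffer compatibility or gel image
  analysis; band sizes are taken as given in bp.
- The thermodynamic layer stops at monovalent salt corrections; Mg²⁺,
  dNTP and dangling-end effects are not modeled.
- The HWE test is the asymptotic 1-df χ²; no exact test is provided.
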