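"""Deterministic synthetic templates and cohorts for the three-SNP assay.

The real genomic flanks of rs1801133, rs1799983 and rs2070744 are not
shipped; instead each assay gets a synthetic diploid template whose
amplicon/cut geometry realizes the published fragment sizes exactly: the
published primers are embedded verbatim at positions giving the published
amplicon lengths (248, 371, 178 bp), and the enzyme recognition site is
planted so that the variant base toggles it and the top-strand cut falls at
the published fragment boundary. Random background bases are rejected and
resampled wherever they would create an extra primer binding site or an
extra recognition site inside the amplicon, so digestion and virtual PCR
are exact by construction.

Allele labels follow the dbSNP naming. For rs1801133 and rs1799983 the
variant base appears literally on the amplicon plus strand (GACTC/GACCC for
HinfI; GGGCTC/GGGCGC for BanII). For rs2070744 the amplicon plus strand is
treated as the opposite strand to the allele naming, so the site-carrying
"T" allele holds a C inside the MspI CCGG site and the "C" allele holds a T
(CTGG, uncut) - the published orientation (T allele cut) is realized as
printed.

Cohorts are simulated under Hardy-Weinberg proportions (p^2, 2pq, q^2) with
a seedable generator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .amplify import Primer, find_binding_sites, load_primer_panel
from .genotyper import SNPAssay, load_assays
from .rflp import RestrictionEnzyme, digest, load_enzymes
from .seq import NucleotideSequence, reverse_complement

BASES = np.array(list("ACGT"))
DEFAULT_FLANK = 60


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of one synthetic assay fixture (coordinates within the amplicon)."""

    snp_id: str
    amplicon_length: int
    site_start: int           # 0-based start of the planted recognition site
    site_sequence: str        # site bases for the cut allele
    snp_offset: int           # 0-based variant position, inside the site span
    allele_bases: Dict[str, str]  # allele symbol -> plus-strand base at snp_offset
    cut_allele: str
    cut_position: int         # top-strand cut coordinate within the amplicon
    flank_length: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if not 0 < self.cut_position < self.amplicon_length:
            raise ValueError(f"{self.snp_id}: cut_position outside amplicon")
        if not (self.site_start <= self.snp_offset
                < self.site_start + len(self.site_sequence)):
            raise ValueError(f"{self.snp_id}: snp_offset outside recognition site")

    @property
    def fragments(self) -> Tuple[int, int]:
        return (max(self.cut_position, self.amplicon_length - self.cut_position),
                min(self.cut_position, self.amplicon_length - self.cut_position))


#: Planted geometry reproducing the published fragment sizes.
#: MTHFR 677: 248 bp amplicon, HinfI cut at 130 -> {130, 118}.
#: eNOS -786: 178 bp amplicon, MspI cut at 137 -> {137, 41}.
#: eNOS +894: 371 bp amplicon, BanII cut at 223 -> {223, 148}; the published
#: small fragment "139" does not conserve the amplicon length and is not
#: realizable (223 + 139 != 371).
FIXTURE_SPECS: Dict[str, FixtureSpec] = {
    "rs1801133": FixtureSpec(
        snp_id="rs1801133", amplicon_length=248,
        site_start=129, site_sequence="GACTC", snp_offset=132,
        allele_bases={"T": "T", "C": "C"},
        cut_allele="T", cut_position=130,
    ),
    "rs2070744": FixtureSpec(
        snp_id="rs2070744", amplicon_length=178,
        site_start=136, site_sequence="CCGG", snp_offset=137,
        allele_bases={"T": "C", "C": "T"},
        cut_allele="T", cut_position=137,
    ),
    "rs1799983": FixtureSpec(
        snp_id="rs1799983", amplicon_length=371,
        site_start=218, site_sequence="GGGCTC", snp_offset=222,
        allele_bases={"T": "T", "G": "G"},
        cut_allele="T", cut_position=223,
    ),
}


@dataclass(frozen=True)
class DiploidTemplate:
    """A synthetic diploid template: two equal-length allele sequences.

    The sequences differ only at the variant position; each yields the
    assay's amplicon under virtual PCR at zero mismatches, and digesting
    each allele's amplicon matches the assay's homozygote band row.
    """

    snp_id: str
    genotype: str
    allele_sequences: Tuple[NucleotideSequence, NucleotideSequence]
    amplicon_start: int
    amplicon_end: int
    seed: int

    def allele_amplicons(self) -> Tuple[NucleotideSequence, NucleotideSequence]:
        return tuple(
            NucleotideSequence(
                id=f"{s.id}_amplicon",
                residues=s.residues[self.amplicon_start:self.amplicon_end],
            )
            for s in self.allele_sequences
        )


class FixtureError(RuntimeError):
    """Raised when a satisfiable template cannot be constructed."""


def _seed_for(snp_id: str, seed: int) -> list:
    # independent, reproducible stream per assay
    return [seed & 0x7FFFFFFF, zlib.crc32(snp_id.encode())]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n)) if n else ""


def _clean_template(residues: str, panel: Sequence[Primer],
                    own: Tuple[str, str], amp_start: int, amp_end: int,
                    enzyme: RestrictionEnzyme, expect_cuts: Tuple[int, ...]
                    ) -> bool:
    """True when the template has exactly the intended primer sites and cuts."""
    template = NucleotideSequence(id="candidate", residues=residues)
    fwd_name, rev_name = own
    for primer in panel:
        sites = find_binding_sites(template, primer, max_mismatches=0)
        if primer.name == fwd_name:
            ok = (len(sites) == 1 and sites[0].strand == "+"
                  and sites[0].start == amp_start)
        elif primer.name == rev_name:
            ok = (len(sites) == 1 and sites[0].strand == "-"
                  and sites[0].end == amp_end)
        else:
            ok = not sites
        if not ok:
            return False
    amplicon = residues[amp_start:amp_end]
    return digest(amplicon, enzyme).cut_positions == expect_cuts


def make_template(assay: SNPAssay, genotype: str, seed: int,
                  flank_length: int = DEFAULT_FLANK,
                  panel: Sequence[Primer] = None,
                  enzymes: Dict[str, RestrictionEnzyme] = None,
                  max_tries: int = 200) -> DiploidTemplate:
    """Build a diploid synthetic template realizing the assay's geometry.

    Deterministic for a fixed (assay, seed); the genotype only selects which
    allele sequences are paired, so all genotypes of one assay share the
    same background sequence.
    """
    if genotype not in assay.genotype_bands:
        raise KeyError(f"unknown genotype {genotype!r} for {assay.snp_id}")
    spec = FIXTURE_SPECS[assay.snp_id]
    panel = panel if panel is not None else load_primer_panel()
    enzymes = enzymes if enzymes is not None else load_enzymes()
    enzyme = enzymes[assay.enzyme_name]
    by_name = {p.name: p for p in panel}
    fwd = by_name[assay.forward_primer].sequence
    rev_rc = reverse_complement(by_name[assay.reverse_primer].sequence)
    amp_len = spec.amplicon_length
    middle_len = amp_len - len(fwd) - len(rev_rc)
    if middle_len < 0:
        raise FixtureError(f"{assay.snp_id}: amplicon shorter than primers")
    site_end = spec.site_start + len(spec.site_sequence)
    if spec.site_start < len(fwd) or site_end > amp_len - len(rev_rc):
        raise FixtureError(
            f"{assay.snp_id}: recognition site overlaps a primer footprint"
        )

    rng = np.random.default_rng(_seed_for(assay.snp_id, seed))
    amp_start = flank_length
    amp_end = flank_length + amp_len

    allele_templates: Dict[str, str] = {}
    for _ in range(max_tries):
        middle = list(_random_bases(rng, middle_len))
        core = list(fwd) + middle + list(rev_rc)
        core[spec.site_start:site_end] = spec.site_sequence
        left = _random_bases(rng, flank_length)
        right = _random_bases(rng, flank_length)
        candidates = {}
        for allele, base in spec.allele_bases.items():
            allele_core = list(core)
            allele_core[spec.snp_offset] = base
            candidates[allele] = left + "".join(allele_core) + right
        expect = {
            allele: ((spec.cut_position,) if allele == spec.cut_allele else ())
            for allele in spec.allele_bases
        }
        if all(_clean_template(t, panel, (assay.forward_primer, assay.reverse_primer),
                               amp_start, amp_end, enzyme, expect[a])
               for a, t in candidates.items()):
            allele_templates = candidates
            break
    else:
        raise FixtureError(
            f"{assay.snp_id}: could not build a clean template in {max_tries} tries"
        )

    a1, a2 = genotype[0], genotype[1]
    seqs = tuple(
        NucleotideSequence(
            id=f"{assay.snp_id}_{genotype}_allele{i}",
            residues=allele_templates[allele],
            description=f"snp={assay.snp_id} genotype={genotype} "
                        f"allele={allele} seed={seed}",
        )
        for i, allele in enumerate((a1, a2), start=1)
    )
    return DiploidTemplate(snp_id=assay.snp_id, genotype=genotype,
                           allele_sequences=seqs, amplicon_start=amp_start,
                           amplicon_end=amp_end, seed=seed)


def three_locus_templates(seed: int, genotypes: Dict[str, str] = None
                          ) -> List[DiploidTemplate]:
    """One template per assay (default genotypes: the uncut homozygotes)."""
    assays = load_assays()
    panel = load_primer_panel()
    enzymes = load_enzymes()
    out = []
    for snp_id, assay in assays.items():
        if genotypes and snp_id in genotypes:
            g = genotypes[snp_id]
        else:
            uncut = next(a for a in assay.alleles if a != assay.cut_allele)
            g = assay.genotype_for_alleles(uncut, uncut)
        out.append(make_template(assay, g, seed, panel=panel, enzymes=enzymes))
    return out


def make_cohort(p: float, n: int, seed: int,
                alleles: Tuple[str, str] = ("A", "a")) -> List[str]:
    """Simulate n diploid genotypes under Hardy-Weinberg proportions.

    Draws are independent with probabilities (p^2, 2pq, q^2) for
    (hom_ref, het, hom_alt); deterministic per seed.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b = alleles
    labels = np.array([a + a, a + b, b + b])
    q = 1.0 - p
    probs = np.array([p * p, 2 * p * q, q * q])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    return list(rng.choice(labels, size=n, p=probs))


def genotype_counts(genotypes: Sequence[str],
                    alleles: Tuple[str, str] = ("A", "a")) -> Tuple[int, int, int]:
    """Tally a genotype list into (hom_ref, het, hom_alt) counts."""
    a, b = alleles
    hom_ref = sum(1 for g in genotypes if g == a + a)
    hom_alt = sum(1 for g in genotypes if g == b + b)
    het = len(genotypes) - hom_ref - hom_alt
    return hom_ref, het, hom_alt
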