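"""Assay definitions and band-pattern -> genotype calling.

An :class:`SNPAssay` is the machine form of the published genotype/band
table: for each SNP it records the primer pair, amplicon size, enzyme and
the three genotypes' expected band sets. :func:`call_genotype` matches an
observed lane against those sets under a gel model (size tolerance plus a
detection limit below which small fragments run off or are invisible);
:func:`call_lane` first partitions a multiplexed lane's bands among assays
by nearest expected size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

AMBIGUOUS = "ambiguous"
NO_CALL = "no_call"


@dataclass(frozen=True)
class GelModel:
    """Gel calling parameters.

    size_tolerance
        Absolute band-size matching tolerance in bp. Default 5 bp
        (high-resolution agarose discriminates ~10 bp in this size range).
    min_detectable
        Smallest band reliably visible, in bp; default 30 (the size ladder
        starts at 25 bp).
    ladder
        Rung sizes of the size standard, informational only.
    """

    size_tolerance: float = 5.0
    min_detectable: float = 30.0
    ladder: Tuple[int, ...] = (25, 50, 75, 100, 150, 200, 300, 400, 500, 700)

    def __post_init__(self) -> None:
        if self.size_tolerance < 0 or self.min_detectable < 0:
            raise ValueError("gel parameters must be non-negative")


@dataclass(frozen=True)
class SNPAssay:
    """One PCR-RFLP assay: primers, amplicon, enzyme, genotype -> band table."""

    snp_id: str
    locus_label: str
    forward_primer: str
    reverse_primer: str
    amplicon_length: int
    enzyme_name: str
    alleles: Tuple[str, str]
    cut_allele: str
    genotype_bands: Dict[str, FrozenSet[int]]
    published_bands: Optional[Dict[str, FrozenSet[int]]] = None
    published_note: str = ""

    def __post_init__(self) -> None:
        if len(self.genotype_bands) != 3:
            raise ValueError(f"{self.snp_id}: exactly 3 genotypes required")
        gb = {g: frozenset(b) for g, b in self.genotype_bands.items()}
        object.__setattr__(self, "genotype_bands", gb)
        if self.published_bands is not None:
            object.__setattr__(self, "published_bands",
                               {g: frozenset(b)
                                for g, b in self.published_bands.items()})
        hom_cut, hom_uncut, het = self._classify()
        if gb[het] != gb[hom_cut] | gb[hom_uncut]:
            raise ValueError(
                f"{self.snp_id}: heterozygote bands must be the union of the "
                "two homozygote band sets"
            )
        if sum(gb[hom_cut]) != self.amplicon_length:
            raise ValueError(
                f"{self.snp_id}: cut-allele bands must sum to the amplicon length"
            )

    def _classify(self) -> Tuple[str, str, str]:
        a, b = self.alleles
        hom_cut = self.cut_allele * 2
        uncut_allele = b if self.cut_allele == a else a
        hom_uncut = uncut_allele * 2
        het = next(g for g in self.genotype_bands
                   if g not in (hom_cut, hom_uncut))
        return hom_cut, hom_uncut, het

    @property
    def genotypes(self) -> List[str]:
        return list(self.genotype_bands)

    @property
    def heterozygote(self) -> str:
        return self._classify()[2]

    def genotype_for_alleles(self, a1: str, a2: str) -> str:
        """Map an unordered allele pair onto this assay's genotype key."""
        for g in self.genotype_bands:
            if sorted(g) == sorted(a1 + a2):
                return g
        raise KeyError(f"{self.snp_id}: no genotype for alleles {a1}/{a2}")

    def all_expected_sizes(self) -> FrozenSet[int]:
        sizes: set = set()
        for bands in self.genotype_bands.values():
            sizes |= bands
        return frozenset(sizes)


@dataclass(frozen=True)
class GenotypeCall:
    """Outcome of matching one lane's bands against one assay."""

    snp_id: str
    genotype: str                         # a genotype key, "ambiguous" or "no_call"
    matched_bands: Tuple[float, ...] = ()
    unexplained_bands: Tuple[float, ...] = ()
    flags: Tuple[str, ...] = ()

    @property
    def is_clean(self) -> bool:
        return self.genotype not in (AMBIGUOUS, NO_CALL) and not self.unexplained_bands


def expected_bands(assay: SNPAssay, genotype: str) -> FrozenSet[int]:
    """The assay's expected band sizes for one genotype (table lookup)."""
    try:
        return assay.genotype_bands[genotype]
    except KeyError:
        raise KeyError(
            f"unknown genotype {genotype!r} for {assay.snp_id}; "
            f"expected one of {sorted(assay.genotype_bands)}"
        ) from None


def _match_bands(expected: Sequence[int], observed: Sequence[float],
                 tol: float) -> Optional[List[Tuple[int, float]]]:
    """Pair every expected band with exactly one observed band within tol.

    Returns the pairing, or None when counts differ or any pair exceeds the
    tolerance. Both lists are matched in sorted order, which is exact for
    tolerances smaller than half the spacing between adjacent band sizes.
    """
    if len(expected) != len(observed):
        return None
    exp = sorted(expected)
    obs = sorted(observed)
    pairs = list(zip(exp, obs))
    if all(abs(e - o) <= tol for e, o in pairs):
        return pairs
    return None


def call_genotype(assay: SNPAssay, observed: Sequence[float],
                  gel: GelModel = GelModel()) -> GenotypeCall:
    """Call one assay's genotype from observed band sizes.

    For each candidate genotype, expected bands below the gel's detection
    limit are dropped; the genotype matches when the remaining expected
    bands and the observed bands pair off one-to-one within the size
    tolerance. Exactly one match yields that call, none yields ``no_call``,
    several yield ``ambiguous``.
    """
    observed = [float(b) for b in observed]
    if any(b <= 0 for b in observed):
        raise ValueError("observed band sizes must be positive")
    matches: List[Tuple[str, List[Tuple[int, float]], List[str]]] = []
    for genotype, bands in assay.genotype_bands.items():
        visible = [b for b in bands if b >= gel.min_detectable]
        dropped = sorted(b for b in bands if b < gel.min_detectable)
        pairing = _match_bands(visible, observed, gel.size_tolerance)
        if pairing is not None:
            flags = [f"expected {b} bp band below detection limit "
                     f"({gel.min_detectable:g} bp)" for b in dropped]
            matches.append((genotype, pairing, flags))
    if len(matches) == 1:
        genotype, pairing, flags = matches[0]
        return GenotypeCall(snp_id=assay.snp_id, genotype=genotype,
                            matched_bands=tuple(o for _, o in pairing),
                            flags=tuple(flags))
    if not matches:
        return GenotypeCall(snp_id=assay.snp_id, genotype=NO_CALL,
                            unexplained_bands=tuple(sorted(observed)),
                            flags=("no genotype matches the observed bands",)
                            if observed else ("empty lane",))
    return GenotypeCall(
        snp_id=assay.snp_id, genotype=AMBIGUOUS,
        matched_bands=tuple(sorted(observed)),
        flags=tuple(f"candidate genotype {g}" for g, _, _ in matches),
    )


def validate_panel(assays: Sequence[SNPAssay], gel: GelModel) -> None:
    """Reject multiplex panels whose uncut amplicon sizes are not resolvable."""
    lengths = [(a.snp_id, a.amplicon_length) for a in assays]
    for i, (id1, l1) in enumerate(lengths):
        for id2, l2 in lengths[i + 1:]:
            if abs(l1 - l2) <= gel.size_tolerance:
                raise ValueError(
                    f"assays {id1} and {id2} have indistinguishable amplicon "
                    f"sizes ({l1} vs {l2} bp at tolerance {gel.size_tolerance})"
                )


def call_lane(assays: Sequence[SNPAssay], observed: Sequence[float],
              gel: GelModel = GelModel()) -> List[GenotypeCall]:
    """Call every assay in a multiplexed lane.

    Observed bands are first partitioned among assays by nearest expected
    band size; a band within tolerance of more than one assay's expectations
    is flagged as ambiguous on all those assays (and assigned to the
    nearest). Each assay is then called on its assigned bands.
    """
    validate_panel(assays, gel)
    observed = [float(b) for b in observed]
    assigned: Dict[str, List[float]] = {a.snp_id: [] for a in assays}
    shared_flags: Dict[str, List[str]] = {a.snp_id: [] for a in assays}
    for band in observed:
        dists = [(min(abs(band - e) for e in a.all_expected_sizes()), a.snp_id)
                 for a in assays]
        dists.sort()
        within = [snp for d, snp in dists if d <= gel.size_tolerance]
        best_snp = dists[0][1]
        assigned[best_snp].append(band)
        if len(within) > 1:
            for snp in within:
                shared_flags[snp].append(
                    f"{band:g} bp band is within tolerance of multiple assays "
                    f"({', '.join(within)}); assigned to {best_snp}"
                )
    calls = []
    for assay in assays:
        call = call_genotype(assay, assigned[assay.snp_id], gel)
        extra = tuple(shared_flags[assay.snp_id])
        if extra:
            call = GenotypeCall(snp_id=call.snp_id, genotype=call.genotype,
                                matched_bands=call.matched_bands,
                                unexplained_bands=call.unexplained_bands,
                                flags=call.flags + extra)
        calls.append(call)
    return calls


def load_assays(path=None) -> Dict[str, SNPAssay]:
    """Load assay definitions from JSON; defaults to the packaged three-SNP panel."""
    if path is None:
        with resources.files("rflpsim.data").joinpath("assays.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    assays = {}
    for a in cfg["assays"]:
        assays[a["snp_id"]] = SNPAssay(
            snp_id=a["snp_id"], locus_label=a["locus_label"],
            forward_primer=a["forward_primer"], reverse_primer=a["reverse_primer"],
            amplicon_length=a["amplicon_length"], enzyme_name=a["enzyme"],
            alleles=tuple(a["alleles"]), cut_allele=a["cut_allele"],
            genotype_bands={g: frozenset(b)
                            for g, b in a["genotype_bands"].items()},
            published_bands=({g: frozenset(b)
                              for g, b in a["published_bands"].items()}
                             if "published_bands" in a else None),
            published_note=a.get("published_note", ""),
        )
    return assays
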