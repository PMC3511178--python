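"""Virtual restriction digestion of amplicons.

Recognition sites may be degenerate (IUPAC); cutting is complete and
deterministic, and fragment sizes are top-strand interval lengths (gel
electrophoresis cannot resolve sticky-end overhang asymmetry). A diploid
sample's lane is the union of both alleles' fragments, with co-migrating
equal-length fragments merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, List, Sequence, Tuple

from .seq import NucleotideSequence, find_sites, _as_residues, _validate


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: IUPAC recognition pattern and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", _validate(self.recognition))
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut_offset must lie within the recognition site"
            )


@dataclass(frozen=True)
class DigestResult:
    """Cut positions and fragment lengths for one amplicon/enzyme pair."""

    amplicon_id: str
    enzyme_name: str
    cut_positions: Tuple[int, ...]        # sorted, top-strand, within amplicon
    fragment_lengths: Tuple[int, ...]     # sorted descending

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


@dataclass(frozen=True)
class BandSet:
    """Distinct band sizes in one gel lane (equal-length fragments co-migrate)."""

    snp_id: str
    lengths: FrozenSet[int]

    def sorted_desc(self) -> List[int]:
        return sorted(self.lengths, reverse=True)


def digest(amplicon_seq, enzyme: RestrictionEnzyme,
           amplicon_id: str = "") -> DigestResult:
    """Completely digest a linear sequence with one enzyme.

    Cut positions are ``site.start + cut_offset`` for every recognition hit
    on either strand (deduplicated; cuts falling on the sequence boundary
    are no-ops). Zero hits leave a single fragment spanning the whole
    sequence. Fragment lengths always sum to the input length.
    """
    if isinstance(amplicon_seq, NucleotideSequence):
        residues = amplicon_seq.residues
        amplicon_id = amplicon_id or amplicon_seq.id
    else:
        residues = _as_residues(amplicon_seq)
    n = len(residues)
    hits = find_sites(residues, enzyme.recognition, both_strands=True)
    cuts = sorted({h.start + enzyme.cut_offset for h in hits
                   if 0 < h.start + enzyme.cut_offset < n})
    bounds = [0] + cuts + [n]
    fragments = tuple(sorted((b - a for a, b in zip(bounds, bounds[1:])),
                             reverse=True))
    assert sum(fragments) == n, "fragment lengths must conserve amplicon length"
    return DigestResult(amplicon_id=amplicon_id, enzyme_name=enzyme.name,
                        cut_positions=tuple(cuts), fragment_lengths=fragments)


def diploid_band_set(allele_seqs: Sequence, enzyme: RestrictionEnzyme,
                     snp_id: str = "") -> BandSet:
    """Union of distinct fragment lengths from digesting each allele.

    Both allele sequences must have equal length (the assay models single
    nucleotide substitutions only).
    """
    if len(allele_seqs) != 2:
        raise ValueError("exactly two allele sequences are required")
    a, b = (_as_residues(s) for s in allele_seqs)
    if len(a) != len(b):
        raise ValueError(
            f"allele sequences differ in length ({len(a)} vs {len(b)}): "
            "only substitutions are modeled"
        )
    lengths: set = set()
    for s in (a, b):
        lengths.update(digest(s, enzyme).fragment_lengths)
    return BandSet(snp_id=snp_id, lengths=frozenset(lengths))


def load_enzymes(path=None) -> Dict[str, RestrictionEnzyme]:
    """Load enzyme definitions from JSON; defaults to the packaged set
    (HinfI G^ANTC, MspI C^CGG, BanII GRGCY^C)."""
    if path is None:
        with resources.files("rflpsim.data").joinpath("enzymes.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    enzymes = {}
    for e in cfg["enzymes"]:
        enzymes[e["name"]] = RestrictionEnzyme(
            name=e["name"], recognition=e["recognition"],
            cut_offset=e["cut_offset"],
        )
    return enzymes
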