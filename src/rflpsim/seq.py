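"""IUPAC nucleotide sequences, reverse complement, GC content and motif scanning.

This is the substrate for the rest of the package: templates, primers,
amplicons and restriction-site patterns are all held as
:class:`NucleotideSequence` objects (uppercase IUPAC strings with 0-based,
half-open, plus-strand coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC one-letter code -> set of concrete bases it stands for.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)
UNAMBIGUOUS = frozenset("ACGT")


class SequenceError(ValueError):
    """Raised for invalid residues or operations on unsuitable sequences."""


def _validate(residues: str) -> str:
    upper = residues.upper()
    for i, ch in enumerate(upper):
        if ch not in IUPAC_ALPHABET:
            raise SequenceError(
                f"invalid IUPAC nucleotide {ch!r} at position {i}"
            )
    if not upper:
        raise SequenceError("empty sequence")
    return upper


@dataclass(frozen=True)
class NucleotideSequence:
    """An IUPAC nucleotide string with an identifier.

    Input is case-insensitive; residues are stored uppercase. Coordinates
    into the sequence are 0-based, half-open, on the plus strand.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _validate(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def is_unambiguous(self) -> bool:
        return all(ch in UNAMBIGUOUS for ch in self.residues)


@dataclass(frozen=True)
class MotifHit:
    """A single occurrence of an IUPAC pattern on a sequence.

    ``start`` is the 0-based plus-strand offset of the first matched base;
    minus-strand hits are reported at the plus-strand coordinates of the
    reverse-complement match.
    """

    start: int
    strand: str  # "+" or "-"
    pattern: str


def _as_residues(seq) -> str:
    return seq.residues if isinstance(seq, NucleotideSequence) else _validate(str(seq))


def reverse_complement(seq):
    """IUPAC-aware reverse complement (R<->Y, S<->S, W<->W, K<->M, B<->V, D<->H, N<->N).

    Accepts a :class:`NucleotideSequence` or a plain string and returns the
    same type. Applying the operation twice returns the input.
    """
    if isinstance(seq, NucleotideSequence):
        rc = str(Seq(seq.residues).reverse_complement())
        return NucleotideSequence(id=f"{seq.id}_rc", residues=rc,
                                  description=seq.description)
    return str(Seq(_as_residues(seq)).reverse_complement())


def gc_percent(seq) -> float:
    """GC content in percent for an unambiguous (A/C/G/T) sequence.

    Degenerate codes are rejected: a GC% of an ambiguous sequence is not
    well defined for primer QC purposes.
    """
    residues = _as_residues(seq)
    for i, ch in enumerate(residues):
        if ch not in UNAMBIGUOUS:
            raise SequenceError(
                f"degenerate code {ch!r} at position {i}: GC% requires A/C/G/T only"
            )
    gc = sum(1 for ch in residues if ch in "GC")
    return 100.0 * gc / len(residues)


def pattern_matches_at(residues: str, pattern: str, start: int) -> bool:
    """True when ``pattern`` (IUPAC) matches ``residues`` at ``start``.

    A template base that is itself degenerate matches a pattern position
    only if its IUPAC set is a subset of the pattern position's set
    (conservative: never report a site that may not exist).
    """
    for j, pch in enumerate(pattern):
        base = residues[start + j]
        if not IUPAC_SETS[base] <= IUPAC_SETS[pch]:
            return False
    return True


def find_sites(seq, pattern: str, both_strands: bool = True) -> List[MotifHit]:
    """All occurrences of an IUPAC ``pattern`` on ``seq``.

    Overlapping hits are all reported. With ``both_strands``, minus-strand
    hits are located by scanning the reverse complement of the pattern along
    the plus strand and reported at plus-strand coordinates; for
    self-reverse-complementary patterns the two scans coincide and hits are
    deduplicated by position (reported once, on the plus strand).
    """
    residues = _as_residues(seq)
    pattern = _validate(pattern)
    if len(pattern) > len(residues):
        return []

    hits: List[MotifHit] = []
    n, m = len(residues), len(pattern)
    for i in range(n - m + 1):
        if pattern_matches_at(residues, pattern, i):
            hits.append(MotifHit(start=i, strand="+", pattern=pattern))
    if both_strands:
        rc = reverse_complement(pattern)
        if rc == pattern:
            return hits  # palindromic: minus-strand scan is identical
        plus_starts = {h.start for h in hits}
        for i in range(n - m + 1):
            if pattern_matches_at(residues, rc, i) and i not in plus_starts:
                hits.append(MotifHit(start=i, strand="-", pattern=pattern))
        hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# --- FASTA I/O ---------------------------------------------------------------

def read_fasta(path) -> List[NucleotideSequence]:
    """Read a (multi-record) FASTA file into NucleotideSequence objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(NucleotideSequence(id=rec.id, residues=str(rec.seq),
                                          description=desc))
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns, description preserved."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
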