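"""Virtual (multiplex) PCR: primer binding-site search and amplicon prediction.

A primer binds the plus strand where its sequence matches left-to-right, and
the minus strand where its reverse complement matches; a bounded number of
mismatches is allowed overall but the 3'-terminal clamp window (the final
eight to ten bases, which dominate priming specificity) must be
mismatch-free. An amplicon is any plus-strand site paired with a downstream
minus-strand site whose 5'-to-5' span does not exceed the size cap; both
primers are incorporated into the product, so the product length runs from
the forward primer's 5' base through the reverse primer's 5' base inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .seq import NucleotideSequence, reverse_complement, _as_residues

DEFAULT_MAX_MISMATCHES = 0
DEFAULT_CLAMP_LEN = 8
DEFAULT_MAX_PRODUCT_LEN = 2000


@dataclass(frozen=True)
class Primer:
    """A PCR primer: name and 5'->3' unambiguous sequence."""

    name: str
    sequence: str
    assay: str = ""
    role: str = ""  # "forward" / "reverse" as configured per assay

    def __post_init__(self) -> None:
        seq = _as_residues(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not 10 <= len(seq) <= 50:
            raise ValueError(f"primer {self.name}: length must be 10-50 bases")
        if any(ch not in "ACGT" for ch in seq):
            raise ValueError(f"primer {self.name}: sequence must be unambiguous A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site on a template.

    ``start`` is the 5'-most plus-strand coordinate of the annealed duplex
    (for a minus-strand site the primer's 5' base sits at
    ``start + len(primer) - 1``).
    """

    primer_name: str
    template_id: str
    strand: str  # "+" or "-"
    start: int
    mismatches: int
    three_prime_clamp_ok: bool
    primer_length: int

    @property
    def end(self) -> int:
        return self.start + self.primer_length


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a template (0-based half-open coordinates)."""

    template_id: str
    start: int
    end: int
    sequence: str
    forward_primer_name: str
    reverse_primer_name: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _mismatch_profile(window: str, primer_seq: str) -> List[int]:
    return [i for i, (a, b) in enumerate(zip(window, primer_seq)) if a != b]


def find_binding_sites(template: NucleotideSequence, primer: Primer,
                       max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                       clamp_len: int = DEFAULT_CLAMP_LEN) -> List[BindingSite]:
    """All annealing sites of ``primer`` on ``template``, both strands.

    A site qualifies when the total mismatch count is at most
    ``max_mismatches`` and the 3'-terminal ``clamp_len`` bases of the primer
    are mismatch-free. Sites are sorted by plus-strand coordinate.
    """
    if clamp_len > len(primer):
        raise ValueError("clamp_len must not exceed primer length")
    t = template.residues
    m = len(primer)
    if m > len(t):
        return []
    sites: List[BindingSite] = []
    pseq = primer.sequence
    rcseq = reverse_complement(pseq)
    for i in range(len(t) - m + 1):
        window = t[i:i + m]
        # plus strand: primer 3' end is the rightmost base of the window
        mm = _mismatch_profile(window, pseq)
        if len(mm) <= max_mismatches:
            clamp_ok = all(pos < m - clamp_len for pos in mm)
            if clamp_ok:
                sites.append(BindingSite(primer.name, template.id, "+", i,
                                         len(mm), True, m))
        # minus strand: primer anneals to the plus strand's complement; its
        # 3' end maps to the leftmost base of the window
        mm = _mismatch_profile(window, rcseq)
        if len(mm) <= max_mismatches:
            clamp_ok = all(pos >= clamp_len for pos in mm)
            if clamp_ok:
                sites.append(BindingSite(primer.name, template.id, "-", i,
                                         len(mm), True, m))
    sites.sort(key=lambda s: (s.start, s.strand, s.primer_name))
    return sites


def predict_amplicons(template: NucleotideSequence, primer_panel: Sequence[Primer],
                      max_len: int = DEFAULT_MAX_PRODUCT_LEN,
                      max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                      clamp_len: int = DEFAULT_CLAMP_LEN) -> List[Amplicon]:
    """Enumerate all products implied by the panel's binding sites.

    Every (plus-strand site, downstream minus-strand site) pair over all
    primer pairs (self-pairings included) with a 5'-to-5' span of at most
    ``max_len`` yields one amplicon. Results are sorted by coordinate then
    length.
    """
    if not primer_panel:
        raise ValueError("primer panel is empty")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    all_sites: List[BindingSite] = []
    for primer in primer_panel:
        all_sites.extend(find_binding_sites(template, primer,
                                            max_mismatches, clamp_len))
    plus = [s for s in all_sites if s.strand == "+"]
    minus = [s for s in all_sites if s.strand == "-"]
    out: List[Amplicon] = []
    for f in plus:
        for r in minus:
            start, end = f.start, r.end
            length = end - start
            if r.start < f.start:
                continue
            if length > max_len or length < max(f.primer_length, r.primer_length):
                continue
            out.append(Amplicon(
                template_id=template.id, start=start, end=end,
                sequence=template.residues[start:end],
                forward_primer_name=f.primer_name,
                reverse_primer_name=r.primer_name,
            ))
    out.sort(key=lambda a: (a.start, a.length, a.forward_primer_name))
    return out


@dataclass
class MultiplexReport:
    """Predicted products across templates plus panel-compatibility warnings."""

    amplicons: List[Amplicon] = field(default_factory=list)
    intended: List[Amplicon] = field(default_factory=list)
    unintended: List[Amplicon] = field(default_factory=list)
    dimer_warnings: List[Tuple[str, str]] = field(default_factory=list)

    def to_rows(self) -> List[dict]:
        return [
            {
                "template": a.template_id, "start": a.start, "end": a.end,
                "length": a.length, "forward": a.forward_primer_name,
                "reverse": a.reverse_primer_name,
                "intended": a in self.intended,
            }
            for a in self.amplicons
        ]


def _three_prime_dimer(p1: Primer, p2: Primer, k: int = 3) -> bool:
    """Heuristic primer-dimer flag: mutually complementary 3'-terminal k-mers."""
    tail1 = p1.sequence[-k:]
    tail2 = p2.sequence[-k:]
    return tail1 == reverse_complement(tail2)


def multiplex_report(templates: Iterable[NucleotideSequence],
                     primer_panel: Sequence[Primer],
                     max_len: int = DEFAULT_MAX_PRODUCT_LEN,
                     max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                     clamp_len: int = DEFAULT_CLAMP_LEN,
                     intended_pairs: Optional[Iterable[Tuple[str, str]]] = None
                     ) -> MultiplexReport:
    """Predict all products of a multiplex panel and flag incompatibilities.

    ``intended_pairs`` is the set of (forward, reverse) primer-name pairs the
    assay designs call for; when omitted it is inferred from the primers'
    configured assay/role. Any other product is reported as unintended.
    Primer pairs (including self-pairs) with complementary 3'-terminal
    trinucleotides are flagged as potential primer-dimers.
    """
    report = MultiplexReport()
    if intended_pairs is None:
        by_assay: Dict[str, Dict[str, str]] = {}
        for p in primer_panel:
            if p.assay and p.role:
                by_assay.setdefault(p.assay, {})[p.role] = p.name
        intended_pairs = [
            (d["forward"], d["reverse"]) for d in by_assay.values()
            if "forward" in d and "reverse" in d
        ]
    intended_set = set(intended_pairs)
    for template in templates:
        for amp in predict_amplicons(template, primer_panel, max_len,
                                     max_mismatches, clamp_len):
            report.amplicons.append(amp)
            pair = (amp.forward_primer_name, amp.reverse_primer_name)
            (report.intended if pair in intended_set else report.unintended
             ).append(amp)
    for i, p1 in enumerate(primer_panel):
        for p2 in primer_panel[i:]:
            if _three_prime_dimer(p1, p2):
                report.dimer_warnings.append((p1.name, p2.name))
    return report


def load_primer_panel(path=None) -> List[Primer]:
    """Load a primer panel from JSON; defaults to the packaged six-primer panel."""
    if path is None:
        with resources.files("rflpsim.data").joinpath("primers.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    return [Primer(name=p["name"], sequence=p["sequence"],
                   assay=p.get("assay", ""), role=p.get("role", ""))
            for p in cfg["panel"]]
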