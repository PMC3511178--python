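"""Cohort genotype statistics: allele frequencies and Hardy-Weinberg checks.

Given genotype counts or frequencies for a biallelic SNP, this module
computes allele frequencies by gene counting (p = f(hom) + f(het)/2), the
Hardy-Weinberg expected genotype proportions (p^2, 2pq, q^2), and a
one-degree-of-freedom chi-square goodness-of-fit test of the observed counts
against those expectations (alleles estimated from the data). Internal
arithmetic is full precision; reporting rounds half-up to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

FREQ_SUM_TOL = 0.01  # published rows are rounded to 2 decimals


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.125 -> 0.13), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeTally:
    """Genotype counts or frequencies for one SNP.

    Order is (hom_ref, het, hom_alt) where "ref" is the assay's first
    allele. Provide ``counts`` (with n inferred) or ``frequencies`` (with
    optional n); frequencies must sum to 1 within 0.01.
    """

    snp_id: str
    counts: Optional[Tuple[int, int, int]] = None
    frequencies: Optional[Tuple[float, float, float]] = None
    n: Optional[int] = None
    genotype_labels: Tuple[str, str, str] = ("hom_ref", "het", "hom_alt")

    def __post_init__(self) -> None:
        if self.counts is None and self.frequencies is None:
            raise ValueError("provide counts or frequencies")
        if self.counts is not None:
            c = tuple(int(x) for x in self.counts)
            if any(x < 0 for x in c):
                raise ValueError("counts must be non-negative")
            object.__setattr__(self, "counts", c)
            object.__setattr__(self, "n", sum(c))
            if sum(c) == 0:
                raise ValueError("all-zero tally")
            object.__setattr__(self, "frequencies",
                               tuple(x / sum(c) for x in c))
        else:
            f = tuple(float(x) for x in self.frequencies)
            if any(x < 0 for x in f):
                raise ValueError("frequencies must be non-negative")
            if abs(sum(f) - 1.0) > FREQ_SUM_TOL:
                raise ValueError(
                    f"genotype frequencies sum to {sum(f):.4f}, not 1 "
                    f"(tolerance {FREQ_SUM_TOL})"
                )
            if sum(f) == 0:
                raise ValueError("all-zero tally")
            object.__setattr__(self, "frequencies", f)


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele frequencies p (first allele) and q = 1 - p for one SNP."""

    snp_id: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")

    def rounded(self) -> Tuple[float, float]:
        return round_half_up(self.p), round_half_up(self.q)


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg goodness-of-fit for one SNP (df = 1)."""

    snp_id: str
    expected_frequencies: Tuple[float, float, float]  # (p^2, 2pq, q^2)
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    degenerate: bool = False


def allele_frequencies(tally: GenotypeTally) -> AlleleFrequencies:
    """Gene-counting allele frequencies: p = f(hom_ref) + f(het)/2."""
    f0, f1, _ = tally.frequencies
    total = sum(tally.frequencies)
    p = (f0 + f1 / 2.0) / total  # renormalize rounded rows so p + q == 1 exactly
    return AlleleFrequencies(snp_id=tally.snp_id, p=p, q=1.0 - p)


def hwe_expected(freqs: AlleleFrequencies) -> Tuple[float, float, float]:
    """Hardy-Weinberg expected genotype frequencies (p^2, 2pq, q^2)."""
    p, q = freqs.p, freqs.q
    return (p * p, 2.0 * p * q, q * q)


def hwe_chisq(tally: GenotypeTally,
              freqs: Optional[AlleleFrequencies] = None) -> HWEResult:
    """Chi-square goodness-of-fit of observed genotype counts against HWE.

    Allele frequencies are estimated from the data unless supplied. The
    statistic sums (obs - n*exp)^2 / (n*exp) over the three genotype
    classes; one degree of freedom (three classes, one estimated allele
    frequency, one constraint). Classes with zero expectation (monomorphic
    samples) are skipped and flagged as degenerate.
    """
    if tally.counts is None:
        raise ValueError("hwe_chisq requires integer genotype counts")
    if freqs is None:
        freqs = allele_frequencies(tally)
    n = tally.n
    expected = hwe_expected(freqs)
    chi2 = 0.0
    degenerate = False
    for obs, exp_f in zip(tally.counts, expected):
        exp = n * exp_f
        if exp == 0.0:
            degenerate = True
            continue
        chi2 += (obs - exp) ** 2 / exp
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(snp_id=tally.snp_id, expected_frequencies=expected,
                     chi_square=chi2, degrees_of_freedom=1, p_value=p_value,
                     degenerate=degenerate)


def load_published_cohort(path=None, use_counts: bool = False
                          ) -> List[GenotypeTally]:
    """Load the packaged healthy-cohort genotype-frequency rows (n = 114).

    The source prints frequencies only; ``use_counts`` switches to the
    reconstructed integer counts round(freq * n), which are approximate
    (they need not sum exactly to n) and are intended for demonstrating the
    chi-square path, not for re-deriving the published frequencies.
    """
    if path is None:
        with resources.files("rflpsim.data").joinpath("cohort_malay.json").open() as fh:
            cfg = json.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    tallies = []
    for row in cfg["cohorts"]:
        labels = tuple(row["genotypes"])
        if use_counts:
            tallies.append(GenotypeTally(snp_id=row["snp_id"],
                                         counts=tuple(row["reconstructed_counts"]),
                                         genotype_labels=labels))
        else:
            tallies.append(GenotypeTally(snp_id=row["snp_id"],
                                         frequencies=tuple(row["frequencies"]),
                                         n=cfg["n"], genotype_labels=labels))
    return tallies


def cohort_allele_labels(tallies: Sequence[GenotypeTally]) -> Dict[str, Tuple[str, str]]:
    """Infer (first, second) allele symbols from homozygote genotype labels."""
    out = {}
    for t in tallies:
        first, _, last = t.genotype_labels
        if len(set(first)) == 1 and len(set(last)) == 1:
            out[t.snp_id] = (first[0], last[0])
    return out


def cohort_table(tallies: Sequence[GenotypeTally],
                 allele_labels: Optional[Dict[str, Tuple[str, str]]] = None
                 ) -> pd.DataFrame:
    """Per-SNP genotype and allele frequencies, rounded half-up to 2 decimals.

    One row per SNP with the three genotype frequencies, the two allele
    frequencies, and (when counts are available) the HWE chi-square and
    p-value at full precision.
    """
    if not tallies:
        raise ValueError("at least one tally is required")
    rows: List[dict] = []
    for tally in tallies:
        af = allele_frequencies(tally)
        labels = (allele_labels or {}).get(tally.snp_id)
        row = {
            "snp_id": tally.snp_id,
            "n": tally.n,
        }
        for i, (label, f) in enumerate(zip(tally.genotype_labels,
                                           tally.frequencies), start=1):
            row[f"genotype_{i}"] = label
            row[f"genotype_{i}_freq"] = round_half_up(f)
        a1, a2 = labels if labels else ("p", "q")
        row["allele_1"], row["allele_1_freq"] = a1, round_half_up(af.p)
        row["allele_2"], row["allele_2_freq"] = a2, round_half_up(af.q)
        if tally.counts is not None:
            hwe = hwe_chisq(tally, af)
            row["hwe_chi2"] = hwe.chi_square
            row["hwe_p"] = hwe.p_value
            if hwe.degenerate:
                row["hwe_flag"] = "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)
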