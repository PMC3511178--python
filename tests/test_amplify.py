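"""Virtual PCR: binding-site search, amplicon enumeration, panel compatibility."""

import random

import pytest

from rflpsim.amplify import (Amplicon, Primer, find_binding_sites,
                             multiplex_report, predict_amplicons)
from rflpsim.fixtures import make_template, three_locus_templates
from rflpsim.seq import NucleotideSequence, reverse_complement
from .conftest import PRIMERS


def _template(residues, id="t"):
    return NucleotideSequence(id=id, residues=residues)


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def brute_force_sites(template, primer, max_mismatches, clamp_len):
    """Sliding-window comparator, written independently of the implementation."""
    t, p = template, primer
    rc = reverse_complement(p)
    out = []
    for i in range(len(t) - len(p) + 1):
        w = t[i:i + len(p)]
        mm = [j for j in range(len(p)) if w[j] != p[j]]
        if len(mm) <= max_mismatches and all(j < len(p) - clamp_len for j in mm):
            out.append((i, "+"))
        mm = [j for j in range(len(p)) if w[j] != rc[j]]
        if len(mm) <= max_mismatches and all(j >= clamp_len for j in mm):
            out.append((i, "-"))
    return sorted(out)


class TestBindingSites:
    def test_planted_forward_site(self):
        rng = random.Random(0)
        t = _template(_rand(rng, 50) + PRIMERS["677F"] + _rand(rng, 50))
        sites = find_binding_sites(t, Primer("677F", PRIMERS["677F"]))
        assert [(s.start, s.strand) for s in sites] == [(50, "+")]

    def test_planted_reverse_site(self):
        rng = random.Random(1)
        rc = reverse_complement(PRIMERS["677R"])
        t = _template(_rand(rng, 30) + rc + _rand(rng, 30))
        sites = find_binding_sites(t, Primer("677R", PRIMERS["677R"]))
        assert [(s.start, s.strand) for s in sites] == [(30, "-")]

    def test_mismatch_in_clamp_disqualifies(self):
        p = Primer("p", "GATCCGATTACGATCCTTGA")
        mutated = list(p.sequence)
        mutated[-1] = "C"  # 3'-terminal mismatch
        t = _template("TTTT" + "".join(mutated) + "TTTT")
        assert find_binding_sites(t, p, max_mismatches=2, clamp_len=8) == []
        # the same substitution outside the clamp window is tolerated
        mutated = list(p.sequence)
        mutated[2] = "A"
        t = _template("TTTT" + "".join(mutated) + "TTTT")
        sites = find_binding_sites(t, p, max_mismatches=2, clamp_len=8)
        assert [(s.start, s.strand, s.mismatches) for s in sites] == [(4, "+", 1)]

    def test_primer_longer_than_template_is_empty(self):
        t = _template("ACGTACGT")
        assert find_binding_sites(t, Primer("p", "ACGTACGTACGTACGT")) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_brute_force(self, max_mm):
        rng = random.Random(99)
        primer = Primer("p", "GATTACAGATTACAG")
        # plant exact and near copies in a random background
        body = _rand(rng, 5000)
        body = (body[:1000] + primer.sequence + body[1000:3000]
                + reverse_complement(primer.sequence) + body[3000:])
        t = _template(body)
        sites = find_binding_sites(t, primer, max_mismatches=max_mm, clamp_len=8)
        assert [(s.start, s.strand) for s in sites] == \
               brute_force_sites(t.residues, primer.sequence, max_mm, 8)

    def test_monotone_in_mismatch_budget(self):
        rng = random.Random(5)
        t = _template(_rand(rng, 4000))
        primer = Primer("p", "ACGTAGCTAGCT")
        counts = [len(find_binding_sites(t, primer, max_mismatches=k, clamp_len=4))
                  for k in range(4)]
        assert counts == sorted(counts)


class TestPredictAmplicons:
    def test_mthfr_fixture_single_product(self, assays, panel):
        t = make_template(assays["rs1801133"], "CC", seed=1)
        pair = [p for p in panel if p.name in ("677F", "677R")]
        amps = predict_amplicons(t.allele_sequences[0], pair)
        assert [a.length for a in amps] == [248]

    def test_three_locus_multiplex_products(self, panel):
        templates = [t.allele_sequences[0] for t in three_locus_templates(seed=1)]
        lengths = sorted(
            a.length for t in templates for a in predict_amplicons(t, panel))
        assert lengths == [178, 248, 371]

    def test_no_binding_sites_no_products(self, panel):
        t = _template("A" * 300)
        assert predict_amplicons(t, panel) == []

    def test_amplicon_anchored_by_both_primers(self, assays, panel):
        by_name = {p.name: p for p in panel}
        for snp_id, assay in assays.items():
            t = make_template(assay, assay.heterozygote, seed=2)
            amps = predict_amplicons(t.allele_sequences[0], panel)
            assert len(amps) == 1
            a = amps[0]
            fwd = by_name[a.forward_primer_name].sequence
            rev = by_name[a.reverse_primer_name].sequence
            assert a.sequence.startswith(fwd)
            assert a.sequence.endswith(reverse_complement(rev))
            assert a.length == a.end - a.start == assay.amplicon_length

    def test_all_pairs_oracle_on_planted_sites(self):
        """Count and coordinates equal an exhaustive pairing enumeration."""
        rng = random.Random(21)
        f = Primer("f", "GATTACAGATTAC")
        r = Primer("r", "CCATGGTACCATG")
        body = _rand(rng, 2000)
        # plant: f at 100, rc(r) at 600, f at 1200, rc(f) at 1700
        body = (body[:100] + f.sequence + body[113:600]
                + reverse_complement(r.sequence) + body[613:1200]
                + f.sequence + body[1213:1700]
                + reverse_complement(f.sequence) + body[1713:])
        t = _template(body)
        amps = predict_amplicons(t, [f, r], max_len=2000)
        sites = []
        for p in (f, r):
            sites += [(s.start, s.end, s.strand, s.primer_name)
                      for s in find_binding_sites(t, p)]
        expected = sorted(
            (fs, re_) for fs, fe, fstrand, _ in sites if fstrand == "+"
            for rs, re_, rstrand, _ in sites if rstrand == "-"
            if rs >= fs and re_ - fs <= 2000 and re_ - fs >= 13)
        assert sorted((a.start, a.end) for a in amps) == expected
        # includes the f/f self-pairing spanning 100 -> 1713
        assert any(a.forward_primer_name == a.reverse_primer_name == "f"
                   for a in amps)


class TestMultiplexReport:
    def test_packaged_panel_on_fixtures_is_clean(self, panel):
        templates = [t.allele_sequences[0] for t in three_locus_templates(seed=1)]
        report = multiplex_report(templates, panel)
        assert len(report.intended) == 3
        assert report.unintended == []
        assert report.dimer_warnings == []

    def test_dimer_warning_for_complementary_tails(self):
        p1 = Primer("polyA", "AAAAAAAAAAAAAAA")
        p2 = Primer("polyT", "TTTTTTTTTTTTTTT")
        report = multiplex_report([], [p1, p2])
        assert ("polyA", "polyT") in report.dimer_warnings

    def test_empty_template_list(self, panel):
        report = multiplex_report([], panel)
        assert report.amplicons == [] and report.unintended == []
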