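"""Assay prediction: in-silico PCR, genotyping, RT-PCR, consequences."""

import numpy as np
import pytest

from lavlocus.assays import (
    BandPattern,
    Primer,
    annotate_consequences,
    call_genotype,
    genotyping_bands,
    insilico_pcr,
    predict_rt_pcr,
)
from lavlocus.engine import (
    Event,
    apply_event,
    identity_painting,
    render_sequence,
    revcomp,
)
from lavlocus.region import GeneModel, RegionMap
from lavlocus.simulate import genotyping_primers, panel_calls

from conftest import random_scenario


def bruteforce_pcr(wt_seq: str, allele_seq: str, primers, max_product=5000):
    """Independent oracle: string-search primer sequences on the rendered
    allele and pair up facing hits."""
    sites = []  # (name, start, end, strand on allele)
    for p in primers:
        pseq = wt_seq[p.wt_start:p.wt_end]
        if p.strand == "-":
            pseq = revcomp(pseq)
        fwd, rev = pseq, revcomp(pseq)
        i = allele_seq.find(fwd)
        while i != -1:
            sites.append((p.name, i, i + len(fwd), "+"))
            i = allele_seq.find(fwd, i + 1)
        i = allele_seq.find(rev)
        while i != -1:
            sites.append((p.name, i, i + len(rev), "-"))
            i = allele_seq.find(rev, i + 1)
    out = set()
    for n1, s1, e1, st1 in sites:
        for n2, s2, e2, st2 in sites:
            if st1 == "+" and st2 == "-" and s1 < s2 and e2 - s1 <= max_product:
                out.add((n1, n2, e2 - s1))
    return out


class TestInsilicoPCR:
    def test_two_facing_primers_one_product(self):
        p = identity_painting(2000)
        primers = [Primer("f", 100, 120, "+"), Primer("r", 480, 500, "-")]
        prods = insilico_pcr(p, primers)
        assert [(x.fwd, x.rev, x.size) for x in prods] == [("f", "r", 400)]

    def test_outward_facing_no_product(self):
        p = identity_painting(2000)
        primers = [Primer("f", 480, 500, "+"), Primer("r", 100, 120, "-")]
        assert insilico_pcr(p, primers) == []

    def test_primer_split_by_junction_unbindable(self, lav60):
        bp1 = lav60.region.breakpoints["BP1"]
        straddling = Primer("x", bp1 - 10, bp1 + 10, "+")
        downstream = Primer("y", bp1 + 300, bp1 + 320, "-")
        assert insilico_pcr(lav60.truth.painting, [straddling, downstream]) == []

    def test_matches_sequence_scan_oracle_on_fixture(self, lav60):
        """Dual route: painting-based PCR == brute-force scan of the
        rendered sequences, for the genotyping primers on both alleles."""
        primers = genotyping_primers(lav60.region.breakpoints)
        for painting in (identity_painting(lav60.region.length_bp),
                         lav60.truth.painting):
            allele_seq = render_sequence(lav60.wt_seq, painting)
            got = {(x.fwd, x.rev, x.size) for x in insilico_pcr(painting, primers)}
            assert got == bruteforce_pcr(lav60.wt_seq, allele_seq, primers)

    def test_panel_calls_match_sequence_oracle_on_random_scenarios(self, lav60):
        """Screening calls derived from paintings equal brute-force PCR on
        the rendered allele, across random rearrangements of the fixture."""
        from lavlocus.simulate import amplicon_primers

        rng = np.random.default_rng(17)
        for _ in range(5):
            _, events, painting = random_scenario(
                rng, min_len=lav60.region.length_bp,
                max_len=lav60.region.length_bp, max_events=2, min_sep=1000)
            allele_seq = render_sequence(lav60.wt_seq, painting)
            calls = panel_calls(lav60.panel, painting)
            for a in lav60.panel.amplicons:
                prods = bruteforce_pcr(lav60.wt_seq, allele_seq,
                                       amplicon_primers(a))
                assert (calls[a.name] == "present") == bool(prods), a.name


class TestGenotyping:
    def test_lav60_three_primer_design(self, lav60):
        primers = genotyping_primers(lav60.region.breakpoints)
        wt = identity_painting(lav60.region.length_bp)
        lav = lav60.truth.painting
        wt_products = insilico_pcr(wt, primers)
        lav_products = insilico_pcr(lav, primers)
        assert [(p.fwd, p.rev, p.size) for p in wt_products] == [("Gen_F", "Gen_wt_R", 423)]
        assert [(p.fwd, p.rev, p.size) for p in lav_products] == [("Gen_F", "Gen_lav_R", 630)]
        assert call_genotype(genotyping_bands([wt, wt], primers), 423, 630) == "+/+"
        assert call_genotype(genotyping_bands([lav, lav], primers), 423, 630) == "lav/lav"
        assert call_genotype(genotyping_bands([wt, lav], primers), 423, 630) == "lav/+"

    @pytest.mark.parametrize(
        "sizes,expected",
        [({423}, "+/+"), ({630}, "lav/lav"), ({423, 630}, "lav/+"),
         (set(), "no-call"), ({431}, "+/+"), ({900}, "no-call")],
    )
    def test_call_table(self, sizes, expected):
        assert call_genotype(BandPattern(frozenset(sizes)), 423, 630) == expected

    def test_overlapping_expected_sizes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            call_genotype(BandPattern(frozenset()), 423, 440)


class TestConsequences:
    def test_identity_all_intact(self, lav60):
        cons = annotate_consequences(lav60.region, identity_painting(lav60.region.length_bp))
        assert all(c.status == "intact" for c in cons)

    def test_lav60_gene_fates(self, lav60):
        cons = {c.gene: c for c in annotate_consequences(lav60.region, lav60.truth.painting)}
        assert cons["MLPH"].status == "truncated"
        assert cons["MLPH"].retained_exons == tuple(range(1, 10))
        assert cons["PRLH"].status == "deleted" and cons["PRLH"].retained_exons == ()
        assert cons["RAB17"].status != "intact"
        assert cons["LRRFIP1"].status != "deleted"

    def test_internal_exon_deletion_truncates(self):
        gene = GeneModel("MLPH", "+", ((100, 200), (300, 400), (500, 600)))
        region = RegionMap(1000, (gene,), {})
        painting = apply_event(identity_painting(1000), Event("deletion", 250, 450))
        c = annotate_consequences(region, painting)[0]
        assert c.status == "truncated"
        assert c.retained_exons == (1, 3)


class TestRTPCR:
    def test_wild_type_all_amplify(self, lav60):
        gene = lav60.region.gene("MLPH")
        wt = identity_painting(lav60.region.length_bp)
        res = predict_rt_pcr(gene, wt, [(1, 2), (5, 7), (1, 10)])
        assert set(res.values()) == {"amplify"}

    def test_lav60_mlph_pattern_matches_published_outcomes(self, lav60):
        gene = lav60.region.gene("MLPH")
        res = predict_rt_pcr(gene, lav60.truth.painting,
                             [(1, 2), (5, 7), (1, 7), (8, 10), (1, 10), (5, 10)])
        assert res == {(1, 2): "amplify", (5, 7): "amplify", (1, 7): "amplify",
                       (8, 10): "fail", (1, 10): "fail", (5, 10): "fail"}

    def test_lav60_rab17_fails(self, lav60):
        gene = lav60.region.gene("RAB17")
        res = predict_rt_pcr(gene, lav60.truth.painting, [(1, 4), (3, 4)])
        assert set(res.values()) == {"fail"}

    def test_bad_exon_pair_rejected(self, lav60):
        gene = lav60.region.gene("RAB17")
        with pytest.raises(ValueError):
            predict_rt_pcr(gene, lav60.truth.painting, [(0, 4)])
        with pytest.raises(ValueError):
            predict_rt_pcr(gene, lav60.truth.painting, [(2, 9)])
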