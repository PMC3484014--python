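"""Fixture generators: determinism, validity, failure modes."""

import filecmp

import numpy as np
import pytest

from lavlocus.breakpoints import interpret_walk
from lavlocus.engine import Event, apply_event, identity_painting
from lavlocus.region import load_region, read_fasta
from lavlocus.simulate import (
    FixtureConfig,
    GenerationError,
    PhenotypeConfig,
    figure2_panel,
    lav60_breakpoints,
    lav60_events,
    make_allele_and_reads,
    make_panel_and_calls,
    make_phenotypes,
    make_region,
    panel_calls,
    random_panel,
)


class TestRegionGeneration:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cfg = FixtureConfig(seed=7)
        make_region(cfg, outdir=str(d1))
        make_region(cfg, outdir=str(d2))
        for name in ("region.fa", "region.gff3", "breakpoints.tsv"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_written_fixture_reloads_and_validates(self, tmp_path):
        cfg = FixtureConfig(seed=7)
        region, seq = make_region(cfg, outdir=str(tmp_path))
        back = load_region(str(tmp_path / "region.gff3"),
                           str(tmp_path / "breakpoints.tsv"))
        assert back == region
        assert read_fasta(str(tmp_path / "region.fa")) == seq
        assert len(back.gene("MLPH").exons) == 10

    def test_infeasible_gene_placement_raises(self):
        bp = dict(lav60_breakpoints())
        bp["BP2"] = bp["BP1"] + 2000  # too small to hold PRLH
        bp["BP3"] = bp["BP1"] + 2500
        with pytest.raises(GenerationError, match="PRLH|RAB17"):
            make_region(FixtureConfig(seed=0, breakpoints=bp))

    def test_unique_kmers_across_strands(self, lav60):
        k = lav60.config.kmer
        seq = lav60.wt_seq
        from lavlocus.engine import revcomp

        fwd = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        assert len(fwd) == len(seq) - k + 1
        rc = revcomp(seq)
        assert not fwd & {rc[i:i + k] for i in range(len(rc) - k + 1)}


class TestAlleleAndReads:
    def test_identity_events_reads_map_to_single_locations(self, lav60):
        derived, reads, truth = make_allele_and_reads(
            lav60.region, lav60.wt_seq, events=[], config=lav60.config)
        assert derived == lav60.wt_seq
        for read in reads.values():
            assert interpret_walk(read, lav60.wt_seq).n_locations == 1

    def test_seeded_reads_deterministic(self, lav60):
        d2, r2, _ = make_allele_and_reads(lav60.region, lav60.wt_seq,
                                          lav60.events, lav60.config)
        assert d2 == lav60.derived_seq
        assert r2 == lav60.reads

    def test_read_too_short_raises_with_minimum(self, lav60):
        cfg = FixtureConfig(seed=0, read_len=100)
        with pytest.raises(GenerationError, match="needs >="):
            make_allele_and_reads(lav60.region, lav60.wt_seq, lav60.events, cfg)

    def test_walkdown_read_contains_fragment_length(self, lav60):
        m = interpret_walk(lav60.reads["walk_down"], lav60.wt_seq)
        assert m.blocks[1].length == 246


class TestPanel:
    def test_default_panel_pattern_4_8_4(self, lav60):
        names = [a.name for a in lav60.panel.amplicons]
        assert names == list("ABCDEFGHIJKLMNOP")
        calls = [lav60.mut_calls[n] for n in names]
        assert calls == ["present"] * 4 + ["absent"] * 8 + ["present"] * 4
        assert all(v == "present" for v in lav60.wt_calls.values())

    def test_flanking_amplicons_within_1kb_of_breakpoints(self, lav60):
        bp = lav60.region.breakpoints
        amps = {a.name: a for a in lav60.panel.amplicons}
        assert bp["BP1"] - amps["D"].rev_pos < 1000
        assert amps["E"].rev_pos - bp["BP1"] < 1000
        assert bp["BP2"] - amps["L"].fwd_pos < 1000
        assert amps["M"].fwd_pos - bp["BP2"] < 1000

    def test_wild_type_painting_all_present(self, lav60):
        calls = panel_calls(lav60.panel, identity_painting(lav60.region.length_bp))
        assert set(calls.values()) == {"present"}

    def test_amplicon_straddling_deletion_edge_absent(self):
        L = 10000
        painting = apply_event(identity_painting(L), Event("deletion", 4000, 6000))
        panel = random_panel(L, 4, 2000, amplicon_len=400, start=500)
        # amplicon at [4500, 4900) lies inside the deleted interval
        calls = panel_calls(panel, painting)
        inside = [a.name for a in panel.amplicons if 4000 <= a.fwd_pos < 6000]
        assert inside and all(calls[n] == "absent" for n in inside)

    def test_panel_exceeding_region_raises(self):
        with pytest.raises(GenerationError, match="exceeds"):
            random_panel(5000, 10, 1000)

    def test_explicit_spacing_mode(self, lav60):
        panel, wt_calls, mut_calls = make_panel_and_calls(
            lav60.region, lav60.truth.painting, n_amplicons=10, spacing=2500,
            jitter=200, seed=5)
        assert len(panel) == 10
        assert set(wt_calls.values()) == {"present"}


class TestPhenotypes:
    def test_same_seed_identical_tables(self):
        a = make_phenotypes(PhenotypeConfig(), seed=11)
        b = make_phenotypes(PhenotypeConfig(), seed=11)
        assert a.equals(b)

    def test_cohort_structure(self):
        df = make_phenotypes(PhenotypeConfig(), seed=11)
        assert df.groupby("genotype").size().to_dict() == {"lav/+": 66, "lav/lav": 59}
        on = df[df.on_test]
        assert on.groupby("genotype").size().to_dict() == {"lav/+": 41, "lav/lav": 51}
        assert df["family"].nunique() == 21
        assert on["family"].nunique() <= 18
        # egg traits exist only for females
        assert on[on.sex == "M"]["EM"].isna().all()
        assert on[on.sex == "F"]["EM"].notna().all()

    def test_zero_noise_zero_effects_identical_within_sex(self):
        base = PhenotypeConfig()
        flat = PhenotypeConfig(
            growth_mean_wt=base.growth_mean_lav,
            growth_sd_lav=(0, 0, 0), growth_sd_wt=(0, 0, 0),
            family_sd_frac=0.0, weight_noise_sd=0.0,
            bw_test_mean=(175.0, 175.0), bw_test_sd=0.0,
            bwg_mean=(8.0, 8.0), bwg_sd=0.0,
            egg_number_mean=(19.0, 19.0), egg_number_sd=0.0,
            egg_weight_sd=0.0, rfi_shift=0.0, temp_shift=0.0, temp_sd=0.0,
            bw6_mean=(190.0, 190.0), bw6_sd=0.0, carcass_offset_sd=0.0,
            pectoralis_mean=(13.0, 13.0), pectoralis_sd=0.0,
            liver_mean=(4.2, 4.2), liver_sd=0.0,
        )
        df = make_phenotypes(flat, seed=3)
        on = df[df.on_test]
        for sex in ("F", "M"):
            sub = on[on.sex == sex]
            for col in ("FI", "body_temp", "bw_test", "A_true", "k_true"):
                assert sub[col].nunique() == 1, (sex, col)

    def test_lavender_asymptote_below_wild_type(self):
        df = make_phenotypes(PhenotypeConfig(), seed=11)
        means = df.groupby("genotype")["A_true"].mean()
        assert means["lav/lav"] < means["lav/+"]

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            make_phenotypes(PhenotypeConfig(bwg_sd=-1.0), seed=0)


class TestBreakpointSolving:
    def test_solved_positions_deterministic_and_ordered(self):
        bp = lav60_breakpoints()
        names = [f"BP{i}" for i in range(1, 7)]
        pos = [bp[n] for n in names]
        assert pos == sorted(pos)
        assert bp == lav60_breakpoints()

    def test_events_anchored_on_breakpoints(self, lav60):
        evs = lav60_events(lav60.region)
        assert [e.kind for e in evs] == ["inversion", "inversion", "deletion"]
        assert [e.length for e in evs] == [30900, 16400, 16000]
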