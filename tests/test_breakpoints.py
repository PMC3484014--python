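"""Screening and walk-read interpretation against known truth."""

import numpy as np
import pytest

from lavlocus.breakpoints import (
    Amplicon,
    AmpliconPanel,
    InconsistentReferenceError,
    UnmappableReadError,
    assemble_adjacencies,
    interpret_walk,
    screen,
)
from lavlocus.engine import Event, apply_event, identity_painting, lift_over, revcomp
from lavlocus.simulate import panel_calls, random_panel

from conftest import random_dna, random_scenario


def toy_panel():
    # six amplicons of 100 bp spaced 300 bp apart
    return AmpliconPanel(tuple(
        Amplicon(f"a{i}", 200 + 300 * i, 300 + 300 * i) for i in range(6)
    ))


class TestScreen:
    def test_all_present_no_blocks(self):
        panel = toy_panel()
        calls = {a.name: "present" for a in panel.amplicons}
        blocks, windows = screen(panel, calls, dict(calls))
        assert blocks == [] and windows == []

    def test_absent_in_reference_raises(self):
        panel = toy_panel()
        wt = {a.name: "present" for a in panel.amplicons}
        wt["a2"] = "absent"
        with pytest.raises(InconsistentReferenceError, match="a2"):
            screen(panel, wt, dict(wt))

    def test_two_separated_runs_hand_enumerated(self):
        """Toy panel, absent runs {a1} and {a3,a4}: windows checked by hand.

        Amplicon footprints: a0=[200,300) a1=[500,600) a2=[800,900)
        a3=[1100,1200) a4=[1400,1500) a5=[1700,1800).
        """
        panel = toy_panel()
        wt = {a.name: "present" for a in panel.amplicons}
        mut = dict(wt)
        mut["a1"] = mut["a3"] = mut["a4"] = "absent"
        blocks, windows = screen(panel, wt, mut)
        assert [b[0] for b in blocks] == [["a1"], ["a3", "a4"]]
        spans = [(w.lo, w.hi, w.side) for w in windows]
        assert spans == [
            (300, 600, "proximal"),    # [a0 end, a1 end)
            (500, 800, "distal"),      # [a1 start, a2 start)
            (900, 1200, "proximal"),   # [a2 end, a3 end)
            (1400, 1700, "distal"),    # [a4 start, a5 start)
        ]

    def test_lav60_single_block_subkb_windows(self, lav60):
        blocks, windows = screen(lav60.panel, lav60.wt_calls, lav60.mut_calls,
                                 lav60.region.length_bp)
        assert len(blocks) == 1
        assert blocks[0][0] == list("EFGHIJKL")
        assert len(windows) == 2
        assert all(w.width < 1000 for w in windows)

    def test_windows_contain_true_breakpoints(self):
        """Random panels x random deletions: the windows bracket the truth."""
        rng = np.random.default_rng(21)
        tried = 0
        while tried < 40:
            L = int(rng.integers(8000, 20000))
            spacing = int(rng.integers(700, 1500))
            n = min(12, (L - 1000) // spacing)
            if n < 4:
                continue
            panel = random_panel(L, n, spacing, amplicon_len=400,
                                 jitter=100, seed=int(rng.integers(1 << 30)))
            a = int(rng.integers(0, L - 2000))
            b = int(rng.integers(a + 1000, min(a + 6000, L)))
            painting = apply_event(identity_painting(L), Event("deletion", a, b))
            mut = panel_calls(panel, painting)
            wt = panel_calls(panel, identity_painting(L))
            if any(v == "absent" for v in wt.values()):
                continue
            blocks, windows = screen(panel, wt, mut, L)
            if not blocks:
                continue  # deletion fell between amplicons
            tried += 1
            prox = [w for w in windows if w.side == "proximal"]
            dist = [w for w in windows if w.side == "distal"]
            assert any(w.lo <= a <= w.hi for w in prox), (a, b, windows)
            assert any(w.lo <= b <= w.hi for w in dist), (a, b, windows)


class TestInterpretWalk:
    def test_read_inside_wild_type_single_plus_location(self, lav60):
        read = lav60.wt_seq[1000:1400]
        m = interpret_walk(read, lav60.wt_seq)
        assert m.n_locations == 1
        b = m.blocks[0]
        assert (b.wt_start, b.wt_end, b.strand) == (1000, 1400, 1)

    def test_reverse_read_single_minus_location(self, lav60):
        read = revcomp(lav60.wt_seq[2000:2400])
        m = interpret_walk(read, lav60.wt_seq)
        assert m.n_locations == 1
        assert m.blocks[0].strand == -1
        assert (m.blocks[0].wt_start, m.blocks[0].wt_end) == (2000, 2400)

    def test_unmappable_read_raises(self, lav60):
        rng = np.random.default_rng(5)
        read = random_dna(rng, 200)
        with pytest.raises(UnmappableReadError):
            interpret_walk(read, lav60.wt_seq)

    def test_too_short_read_rejected(self, lav60):
        with pytest.raises(ValueError, match="min_anchor"):
            interpret_walk(lav60.wt_seq[:30], lav60.wt_seq)

    def test_recovers_junction_split_structure(self):
        """Reads across random junctions decompose exactly as lift_over says."""
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 25:
            L, events, painting = random_scenario(rng, min_len=4000, max_len=8000,
                                                  max_events=2, min_sep=600)
            seq = random_dna(rng, L)
            from lavlocus.engine import junctions_of, render_sequence
            js = junctions_of(painting)
            if not js:
                continue
            derived = render_sequence(seq, painting)
            j = js[rng.integers(len(js))]
            lo = max(0, j.derived_pos - 150)
            hi = min(len(derived), j.derived_pos + 150)
            if hi - lo < 80:
                continue
            read = derived[lo:hi]
            try:
                m = interpret_walk(read, seq)
            except UnmappableReadError:
                continue
            checked += 1
            # oracle: strand of each block must equal lift_over of the
            # generating painting at the corresponding derived position
            for b in m.blocks:
                wt, strand = lift_over(painting, lo + b.query_offset)
                assert strand == b.strand
                expect = wt if strand == 1 else wt - (b.length - 1)
                assert expect == b.wt_start


class TestAdjacencies:
    def test_single_pair_one_adjacency(self, lav60):
        m = interpret_walk(lav60.reads["walk_up"], lav60.wt_seq)
        obs = assemble_adjacencies([m])
        assert len(obs) == 1 and obs[0].support == 1

    def test_duplicate_observation_merges_support(self, lav60):
        m = interpret_walk(lav60.reads["walk_up"], lav60.wt_seq)
        obs = assemble_adjacencies([m, m])
        assert len(obs) == 1 and obs[0].support == 2

    def test_lav60_reads_yield_read_covered_junctions(self, lav60):
        """Both walk reads together observe R1 and R2 (with strands), the
        junctions their windows cover."""
        up = interpret_walk(lav60.reads["walk_up"], lav60.wt_seq, source_flank="up")
        down = interpret_walk(lav60.reads["walk_down"], lav60.wt_seq, source_flank="down")
        blocks, windows = screen(lav60.panel, lav60.wt_calls, lav60.mut_calls)
        obs = assemble_adjacencies([up, down], windows)
        assert len(obs) == 2
        # R2 is observed in its native orientation by the walk-up read
        up_pair = frozenset([obs[0].left, obs[0].right])
        assert any(up_pair == frozenset([j.left, j.right])
                   for j in lav60.truth.junctions)
        # the scar adjacency is corroborated by a screening window
        assert any(o.corroborated for o in obs)

    def test_requires_at_least_one_match(self):
        with pytest.raises(ValueError):
            assemble_adjacencies([])
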