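"""Synthetic-data generators: the LAV60 fixture and randomized variants.

Everything the pipeline consumes is generated here from a seed — no
downloads.  The LAV60 fixture emulates the quail *lavender* locus:

* a 70-kb wild-type region carrying MLPH (10 exons, plus strand), PRLH
  (3 exons, minus), RAB17 (4 exons, minus) and LRRFIP1 (5 exons, plus) in
  chromosomal order, with six breakpoints BP1 < ... < BP6 placed by the
  constraint solver from the printed event lengths (offsets from BP1:
  0, 13 800, 13 954, 28 454, 2 200 and 246 bp gaps);
* the derived (lavender) allele produced by three ordered events —
  inversion BP3–BP6 (30.9 kb), overlapping inversion BP2–BP4 (16.4 kb in
  the state where it applies), overlapping deletion BP1–BP5 (16 kb) —
  leaving the 246-bp BP5–BP6 fragment translocated next to the deletion
  scar;
* junction-spanning walk reads from both flanks, a 16-amplicon screening
  panel (A–P) whose central eight amplicons fail on the derived allele,
  the three-primer genotyping design (423-bp wild-type band, 630-bp
  lavender band), and phenotype tables with family/sex/genotype structure.

Sequence content is uniform random with globally unique 20-mers on both
strands (rejection-sampled), so exact walk-read matching is unambiguous —
the breakpoint neighbourhoods carry no repeats.
"""

from __future__ import annotations

import functools
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assays import Primer, insilico_pcr
from .breakpoints import Amplicon, AmpliconPanel, MIN_ANCHOR_DEFAULT
from .engine import (
    Event,
    ScenarioResult,
    SegmentPainting,
    anchored_events,
    apply_scenario,
    identity_painting,
    render_sequence,
    revcomp,
)
from .region import (BreakpointConstraint, GeneModel, RegionMap, write_fasta,
                     write_region)
from .reconstruct import SymbolicEvent, solve_coordinates

__all__ = [
    "PRINTED_LENGTHS",
    "LAV60_EVENT_SPECS",
    "FixtureConfig",
    "PhenotypeConfig",
    "GenerationError",
    "lav60_constraints",
    "lav60_breakpoints",
    "lav60_events",
    "make_region",
    "make_allele_and_reads",
    "make_panel_and_calls",
    "genotyping_primers",
    "make_phenotypes",
]


class GenerationError(ValueError):
    """A fixture cannot be generated under the requested configuration."""


# Printed lengths (bp) that define the LAV60 geometry.  Event lengths are
# measured in the allele state where each event occurs.
PRINTED_LENGTHS = {
    "inversion1": 30900,   # BP3-BP6, state 1
    "inversion2": 16400,   # BP2-BP4, state 2
    "deletion": 16000,     # BP1-BP5, state 3
    "fragment": 246,       # BP5-BP6 surviving translocated fragment
    "thrice": 2200,        # BP4-BP5 segment hit by all three events
    "span": 60000,         # BP1-BP6 overall extent (two significant figures)
    "walk_up": 27600,      # walk-up second match distance from BP1
    "walk_down": 30000,    # walk-down 246-bp fragment distance
}

LAV60_EVENT_SPECS = (
    SymbolicEvent("inversion", "BP3", "BP6"),
    SymbolicEvent("inversion", "BP2", "BP4"),
    SymbolicEvent("deletion", "BP1", "BP5"),
)

ROUND_TOL = 50  # +/- bp on values printed to 0.1-kb precision


def lav60_constraints() -> tuple[list[BreakpointConstraint], list[SymbolicEvent]]:
    """The printed distance constraints and the symbolic event structure."""
    P = PRINTED_LENGTHS
    cons = [
        BreakpointConstraint("distance", ("BP5", "BP6"), P["fragment"], "state1", 0,
                             True, "fragment BP5-BP6 = 246 bp"),
        BreakpointConstraint("distance", ("BP4", "BP5"), P["thrice"], "state1",
                             ROUND_TOL, True, "thrice-affected BP4-BP5 = 2.2 kb"),
        BreakpointConstraint("distance", ("BP3", "BP6"), P["inversion1"], "state1",
                             ROUND_TOL, True, "first inversion 30.9 kb"),
        BreakpointConstraint("distance", ("BP2", "BP4"), P["inversion2"], "state2",
                             ROUND_TOL, True, "second inversion 16.4 kb"),
        BreakpointConstraint("distance", ("BP1", "BP5"), P["deletion"], "state3",
                             ROUND_TOL, True, "deletion 16 kb"),
        BreakpointConstraint("distance", ("BP1", "BP6"), P["span"], "state1",
                             int(P["span"] * 0.1), False, "span 60 kb (soft)"),
        BreakpointConstraint("distance", ("BP1", "BP3"), P["walk_up"], "state1",
                             int(P["walk_up"] * 0.1), False, "walk-up 27.6 kb (soft)"),
        BreakpointConstraint("distance", ("BP3", "BP5"), P["walk_down"], "state1",
                             int(P["walk_down"] * 0.1), False, "walk-down 30 kb (soft)"),
    ]
    return cons, list(LAV60_EVENT_SPECS)


@functools.lru_cache(maxsize=8)
def _solved_breakpoints(region_length: int, bp1_min: int) -> tuple:
    cons, events = lav60_constraints()
    sol = solve_coordinates(cons, events, region_length=region_length,
                            min_position=bp1_min)
    if not sol.feasible:
        raise GenerationError(f"constraint set infeasible: {sol.conflict}")
    return tuple(sorted(sol.positions.items()))


def lav60_breakpoints(region_length: int = 70000, bp1_min: int = 6000) -> dict[str, int]:
    """Breakpoint positions solved from the printed constraints (cached)."""
    return dict(_solved_breakpoints(region_length, bp1_min))


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class PhenotypeConfig:
    """Cohort structure and effect sizes for the phenotype generator.

    Defaults are the published cohort conditions: growth cohort of 59
    lavender / 66 wild-type birds from 21 single-pair families; feed trial
    subset of 51 / 41 from 18 families; genotype means and SDs per trait as
    printed; family effects as once-per-family mean shifts carrying
    ``family_sd_frac`` of each trait SD.
    """

    n_lav: int = 59
    n_wt: int = 66
    n_families: int = 21
    growth_mean_lav: tuple[float, float, float] = (204.4, 221.4, 0.0405)
    growth_mean_wt: tuple[float, float, float] = (215.9, 233.0, 0.0401)
    growth_sd_lav: tuple[float, float, float] = (32.1, 34.3, 0.00604)
    growth_sd_wt: tuple[float, float, float] = (38.3, 39.6, 0.00759)
    family_sd_frac: float = 0.3
    weight_noise_sd: float = 3.0
    ages_days: tuple[int, ...] = tuple(range(7, 64, 7))
    # feed trial
    n_test_lav: int = 51
    n_test_wt: int = 41
    n_test_families: int = 18
    bw_test_mean: tuple[float, float] = (173.3, 178.6)  # (lav, wt) g
    bw_test_sd: float = 23.0
    bwg_mean: tuple[float, float] = (8.7, 6.7)
    bwg_sd: float = 10.8
    egg_number_mean: tuple[float, float] = (19.5, 18.4)
    egg_number_sd: float = 2.7
    egg_weight_mean: float = 9.8
    egg_weight_sd: float = 1.1
    # Metabolic body weight: (body weight in grams)^exponent, so that the
    # printed regression coefficients produce feed intakes on the observed
    # scale (e.g. 6.56 x 177^0.75 ~ 315 g over the 3-week test).
    mbw_exponent: float = 0.75
    female_coefs: tuple[float, float, float, float] = (23.3, 1.50, 6.56, 1.075)
    female_r2: float = 0.57
    male_coefs: tuple[float, float, float] = (255.2, 3.35, 2.91)
    male_r2: float = 0.72
    rfi_shift: float = 42.0  # lavender minus wild-type, g
    temp_mean_wt: float = 41.16
    temp_shift: float = -0.14  # lavender minus wild-type, degrees C
    temp_sd: float = 0.28
    temp_bw_slope: float = 0.002  # degrees C per g, ANCOVA covariate coupling
    # 6-month traits (lav, wt)
    bw6_mean: tuple[float, float] = (187.3, 194.3)
    bw6_sd: float = 21.6
    carcass_offset_mean: float = 7.5
    carcass_offset_sd: float = 2.0
    pectoralis_mean: tuple[float, float] = (12.7, 14.0)
    pectoralis_sd: float = 1.55
    liver_mean: tuple[float, float] = (4.29, 4.10)
    liver_sd: float = 1.8


@dataclass(frozen=True)
class FixtureConfig:
    """Everything needed to generate the full LAV60 fixture from a seed."""

    seed: int = 0
    region_length: int = 70000
    breakpoints: Optional[dict[str, int]] = None  # None -> solve from constraints
    kmer: int = 20
    read_len: int = 700
    walkup_stub: int = 12     # sub-anchor wild-type stub before the scar
    walkdown_reach: int = 300
    walkdown_anchor: int = 300
    n_amplicons: int = 16
    amplicon_len: int = 400
    primer_len: int = 20
    max_product: int = 5000
    phenotypes: PhenotypeConfig = field(default_factory=PhenotypeConfig)

    def resolved_breakpoints(self) -> dict[str, int]:
        if self.breakpoints is not None:
            return dict(self.breakpoints)
        return lav60_breakpoints(self.region_length)


# ---------------------------------------------------------------------------
# Region generation


def _gene_layout(bp: dict[str, int], region_length: int) -> tuple[GeneModel, ...]:
    """Place the four genes relative to the breakpoints.

    Layout satisfies the fixture containment facts: MLPH exons 1-9 proximal
    of BP1 with exon 10 inside the deleted content (BP1 in intron 9); PRLH
    wholly inside the deleted content; RAB17 exon 1 just distal of BP2 with
    exons 2-4 deleted; LRRFIP1 exon 1 inside the first inversion with the
    rest of the gene beyond BP6.  Absolute spacings inside the deleted
    content are free choices.
    """
    BP1, BP2, BP3, BP4, BP6 = bp["BP1"], bp["BP2"], bp["BP3"], bp["BP4"], bp["BP6"]

    if BP1 < 5500:
        raise GenerationError(
            f"BP1={BP1} leaves no room for MLPH exons 1-9 proximal of BP1"
        )
    mlph_exons = tuple((BP1 - 5500 + 600 * i, BP1 - 5500 + 600 * i + 120) for i in range(9))
    mlph_exons += ((BP1 + 400, BP1 + 520),)
    if not mlph_exons[9][1] < BP2:
        raise GenerationError("MLPH exon 10 does not fit inside the deleted content")

    if BP2 - BP1 < 4000:
        raise GenerationError("deleted content too small to contain PRLH")
    prlh = GeneModel(
        "PRLH", "-",
        ((BP1 + 3200, BP1 + 3350), (BP1 + 2600, BP1 + 2700), (BP1 + 2000, BP1 + 2150)),
    )
    if BP3 < BP2 + 800 or BP2 - 2800 <= mlph_exons[9][1]:
        raise GenerationError("RAB17 cannot straddle BP2 as required")
    rab17 = GeneModel(
        "RAB17", "-",
        ((BP2 + 600, BP2 + 750), (BP2 - 1000, BP2 - 900),
         (BP2 - 1900, BP2 - 1800), (BP2 - 2800, BP2 - 2680)),
    )
    if BP4 - 1200 <= BP3:
        raise GenerationError("LRRFIP1 exon 1 does not fit inside the first inversion")
    lrr_exons = [(BP4 - 1200, BP4 - 900)]
    start = BP6 + 2346
    for j in range(4):
        lrr_exons.append((start + 700 * j, start + 700 * j + 150))
    if lrr_exons[-1][1] > region_length:
        raise GenerationError("region too short for LRRFIP1 exons beyond BP6")
    lrrfip1 = GeneModel("LRRFIP1", "+", tuple(lrr_exons))

    return (GeneModel("MLPH", "+", mlph_exons), prlh, rab17, lrrfip1)


def _random_sequence(length: int, seed: int, k: int) -> str:
    """Random sequence with globally unique k-mers on both strands."""
    for attempt in range(10):
        rng = np.random.default_rng(seed + 1000003 * attempt)
        arr = rng.integers(0, 4, size=length)
        seq = "".join("ACGT"[b] for b in arr)
        fwd = {seq[i:i + k] for i in range(length - k + 1)}
        if len(fwd) < length - k + 1:
            continue
        rc = revcomp(seq)
        rck = {rc[i:i + k] for i in range(length - k + 1)}
        if fwd & rck:
            continue
        return seq
    raise GenerationError("could not generate a repeat-free sequence in 10 attempts")


def make_region(config: FixtureConfig, outdir: Optional[str] = None):
    """Generate the wild-type region: (RegionMap, sequence[, files]).

    With ``outdir``, writes ``region.fa`` (FASTA), ``region.gff3`` and
    ``breakpoints.tsv``.  Same seed -> byte-identical outputs.
    """
    bp = config.resolved_breakpoints()
    genes = _gene_layout(bp, config.region_length)
    region = RegionMap(length_bp=config.region_length, genes=genes, breakpoints=bp)
    seq = _random_sequence(config.region_length, config.seed, config.kmer)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(os.path.join(outdir, "region.fa"), "LAV60_wt", seq)
        write_region(region, os.path.join(outdir, "region.gff3"),
                     os.path.join(outdir, "breakpoints.tsv"))
    return region, seq


def lav60_events(region: RegionMap) -> list[Event]:
    """The three ordered events, anchored on the named breakpoints."""
    return anchored_events(
        region.length_bp,
        [(e.kind, e.left, e.right) for e in LAV60_EVENT_SPECS],
        region.breakpoints,
    )


# ---------------------------------------------------------------------------
# Derived allele and walk reads


def make_allele_and_reads(region: RegionMap, wt_seq: str,
                          events: Optional[Sequence[Event]] = None,
                          config: FixtureConfig = FixtureConfig(),
                          outdir: Optional[str] = None):
    """Derived-allele sequence, walk reads, and the truth scenario result.

    The walk-up read runs in the derived forward direction across the
    deletion scar; it starts only ``walkup_stub`` bases (default 12, below
    the matching anchor) proximal of the scar — emulating a nested primer
    whose 3' end sits nearly on the junction — so its reported matches are
    the translocated fragment and then the inverted segment on the opposite
    strand.  The walk-down read is the reverse complement of a window
    spanning both proximal junctions from the distal side, and reports
    three locations with the 246-bp fragment in the middle.
    """
    if events is None:
        events = lav60_events(region)
    truth = apply_scenario(region.length_bp, list(events))
    derived = render_sequence(wt_seq, truth.painting)

    if not truth.junctions:
        reads = {"walk_up": derived[: config.read_len],
                 "walk_down": revcomp(derived[-config.read_len:])}
        if outdir is not None:
            _write_outputs(outdir, derived, reads, truth)
        return derived, reads, truth

    first_j = truth.junctions[0].derived_pos
    second_j = (truth.junctions[1].derived_pos if len(truth.junctions) > 1
                else first_j)
    frag = second_j - first_j

    min_up = config.walkup_stub + frag + 3 * MIN_ANCHOR_DEFAULT
    if config.read_len < min_up:
        raise GenerationError(
            f"walk-up read of {config.read_len} bp cannot span the junction "
            f"cluster; needs >= {min_up} bp"
        )
    up_start = first_j - config.walkup_stub
    walk_up = derived[up_start:up_start + config.read_len]

    reach, anchor = config.walkdown_reach, config.walkdown_anchor
    if min(reach, anchor) < 3 * MIN_ANCHOR_DEFAULT:
        raise GenerationError(
            f"walk-down reach/anchor must be >= {3 * MIN_ANCHOR_DEFAULT} bp"
        )
    window = derived[first_j - reach: second_j + anchor]
    walk_down = revcomp(window)

    reads = {"walk_up": walk_up, "walk_down": walk_down}
    if outdir is not None:
        _write_outputs(outdir, derived, reads, truth)
    return derived, reads, truth


def _write_outputs(outdir: str, derived: str, reads: dict, truth: ScenarioResult):
    os.makedirs(outdir, exist_ok=True)
    write_fasta(os.path.join(outdir, "derived.fa"), "LAV60_lav", derived)
    with open(os.path.join(outdir, "walk_reads.fa"), "w") as fh:
        for name, seq in reads.items():
            fh.write(f">{name}\n{seq}\n")
    with open(os.path.join(outdir, "truth_painting.json"), "w") as fh:
        fh.write(truth.painting.to_json())


# ---------------------------------------------------------------------------
# Amplicon panel


def _amplicon_names(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def figure2_panel(bp: dict[str, int], amplicon_len: int = 400) -> AmpliconPanel:
    """The default 16-amplicon A-P panel, breakpoint-aware.

    Four amplicons proximal of BP1 (A-D, with D within 1 kb of BP1), eight
    inside the deleted content (E-L, with E and L within 1 kb of the
    breakpoints), four distal of BP2 (M-P, with M within 1 kb of BP2).
    """
    BP1, BP2 = bp["BP1"], bp["BP2"]
    la = amplicon_len
    starts = [
        BP1 - 5000, BP1 - 3500, BP1 - 2000, BP1 - 550,          # A-D
        BP1 + 250, BP1 + 1900, BP1 + 3550, BP1 + 5200,          # E-H
        BP1 + 6850, BP1 + 8500, BP1 + 10150, BP2 - 550,         # I-L
        BP2 + 250, BP2 + 1900, BP2 + 3550, BP2 + 5200,          # M-P
    ]
    if starts[0] < 0:
        raise GenerationError("panel extends past the region start")
    amps = tuple(
        Amplicon(name=nm, fwd_pos=s, rev_pos=s + la)
        for nm, s in zip(_amplicon_names(16), starts)
    )
    return AmpliconPanel(amplicons=amps)


def random_panel(region_length: int, n_amplicons: int, spacing: int,
                 amplicon_len: int = 400, jitter: int = 0,
                 seed: int = 0, start: int = 500) -> AmpliconPanel:
    """Evenly spaced panel with optional seeded jitter (for property tests)."""
    if n_amplicons < 4:
        raise GenerationError("need at least 4 amplicons")
    if start + (n_amplicons - 1) * spacing + amplicon_len > region_length:
        raise GenerationError("panel spacing exceeds the region")
    rng = np.random.default_rng(seed)
    starts = []
    for i in range(n_amplicons):
        j = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        starts.append(max(0, start + i * spacing + j))
    amps = tuple(
        Amplicon(name=f"amp{i + 1:02d}", fwd_pos=s, rev_pos=s + amplicon_len)
        for i, s in enumerate(starts)
    )
    return AmpliconPanel(amplicons=amps)


def amplicon_primers(a: Amplicon) -> tuple[Primer, Primer]:
    return (
        Primer(f"{a.name}_F", a.fwd_pos, a.fwd_pos + a.primer_len, "+"),
        Primer(f"{a.name}_R", a.rev_pos - a.primer_len, a.rev_pos, "-"),
    )


def panel_calls(panel: AmpliconPanel, painting: SegmentPainting,
                max_product: int = 5000) -> dict[str, str]:
    """present/absent call per amplicon on one allele, via in-silico PCR."""
    calls = {}
    for a in panel.amplicons:
        products = insilico_pcr(painting, list(amplicon_primers(a)), max_product)
        calls[a.name] = "present" if products else "absent"
    return calls


def make_panel_and_calls(region: RegionMap, painting: SegmentPainting,
                         n_amplicons: int = 16, spacing: Optional[int] = None,
                         jitter: int = 0, seed: int = 0,
                         max_product: int = 5000,
                         outdir: Optional[str] = None):
    """Panel + per-allele calls.

    Default (``spacing=None``) is the breakpoint-aware A-P panel; an
    explicit spacing produces an evenly spaced panel with seeded jitter.
    Calls are computed by in-silico PCR on the wild-type and the supplied
    derived painting, so screening stays self-consistent with the assay
    model.
    """
    if spacing is None:
        panel = figure2_panel(region.breakpoints)
    else:
        panel = random_panel(region.length_bp, n_amplicons, spacing,
                             jitter=jitter, seed=seed)
    wt = identity_painting(region.length_bp)
    wt_calls = panel_calls(panel, wt, max_product)
    mut_calls = panel_calls(panel, painting, max_product)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        rows = [
            (a.name, a.fwd_pos, a.rev_pos, wt_calls[a.name], mut_calls[a.name])
            for a in panel.amplicons
        ]
        pd.DataFrame(rows, columns=["name", "fwd_pos", "rev_pos", "wt_call", "mut_call"]
                     ).to_csv(os.path.join(outdir, "panel_calls.tsv"), sep="\t", index=False)
    return panel, wt_calls, mut_calls


# ---------------------------------------------------------------------------
# Genotyping primers


def genotyping_primers(bp: dict[str, int], primer_len: int = 20) -> list[Primer]:
    """The three-primer test: shared Gen_F, wild-type Gen_wt_R inside the
    deleted content (423-bp product), lavender Gen_lav_R inside the
    inverted content so the 630-bp product spans the deletion scar."""
    BP1, BP3 = bp["BP1"], bp["BP3"]
    return [
        Primer("Gen_F", BP1 - 223, BP1 - 223 + primer_len, "+", "generic"),
        Primer("Gen_wt_R", BP1 + 200 - primer_len, BP1 + 200, "-", "wt-specific"),
        Primer("Gen_lav_R", BP3 - 161, BP3 - 161 + primer_len, "+", "mutant-specific"),
    ]


# ---------------------------------------------------------------------------
# Phenotypes


def make_phenotypes(cfg: PhenotypeConfig = PhenotypeConfig(), seed: int = 0,
                    outdir: Optional[str] = None) -> pd.DataFrame:
    """Per-bird phenotype table with the published cohort structure.

    Growth parameters are drawn per bird around genotype means with family
    mean-shifts (``family_sd_frac`` of each SD) plus individual residuals;
    weekly body weights follow each bird's own monomolecular curve with
    measurement noise.  Feed-test feed intake is built from the printed
    sex-specific regressions with a genotype shift on the residual
    (centered so RFI means match the published group means) and Gaussian
    noise calibrated to the printed regression R-squared.  Body temperature
    carries the published genotype shift and couples weakly to body weight
    for the ANCOVA traits.  All draws come from one seeded generator.
    """
    for name in cfg.__dataclass_fields__:
        if name.endswith("_sd") or name.endswith("_sd_frac") or name == "family_sd_frac":
            if getattr(cfg, name) < 0:
                raise ValueError(f"negative variance config: {name}")
        if name.startswith("growth_sd"):
            if any(v < 0 for v in getattr(cfg, name)):
                raise ValueError(f"negative variance config: {name}")

    rng = np.random.default_rng(seed)
    n = cfg.n_lav + cfg.n_wt
    genotype = np.array(["lav/lav"] * cfg.n_lav + ["lav/+"] * cfg.n_wt)
    family = np.array([f"F{(i % cfg.n_families) + 1:02d}" for i in range(n)])
    sex = np.array([("F" if i % 2 == 0 else "M") for i in range(n)])

    frac = cfg.family_sd_frac
    resid = float(np.sqrt(max(0.0, 1.0 - frac ** 2)))

    fam_names = sorted(set(family))
    fam_growth = {f: rng.normal(0.0, 1.0, size=3) for f in fam_names}
    fam_misc = {f: rng.normal(0.0, 1.0, size=4) for f in fam_names}  # FI, temp, bw, bw6

    rows = []
    for i in range(n):
        lav = genotype[i] == "lav/lav"
        gm = cfg.growth_mean_lav if lav else cfg.growth_mean_wt
        gs = cfg.growth_sd_lav if lav else cfg.growth_sd_wt
        fshift = fam_growth[family[i]]
        A = gm[0] + frac * gs[0] * fshift[0] + resid * gs[0] * rng.normal()
        B = gm[1] + frac * gs[1] * fshift[1] + resid * gs[1] * rng.normal()
        k = gm[2] + frac * gs[2] * fshift[2] + resid * gs[2] * rng.normal()
        A, B, k = max(A, 50.0), max(B, 50.0), max(k, 0.005)
        weights = A - B * np.exp(-k * np.array(cfg.ages_days, dtype=float))
        weights = weights + rng.normal(0.0, cfg.weight_noise_sd, size=len(weights))
        row = {
            "bird_id": f"Q{i + 1:03d}", "family": family[i], "sex": sex[i],
            "genotype": genotype[i], "A_true": A, "B_true": B, "k_true": k,
        }
        for t, w in zip(cfg.ages_days, weights):
            row[f"bw_d{t}"] = w
        rows.append(row)
    df = pd.DataFrame(rows)

    # feed-test subset: first n_test_families families, table ns per genotype
    test_fams = set(fam_names[: cfg.n_test_families])
    on_test = np.zeros(n, dtype=bool)
    for geno, quota in (("lav/lav", cfg.n_test_lav), ("lav/+", cfg.n_test_wt)):
        idx = [i for i in range(n) if genotype[i] == geno and family[i] in test_fams]
        for i in idx[:quota]:
            on_test[i] = True
    df["on_test"] = on_test

    bw_test = np.where(
        genotype == "lav/lav", cfg.bw_test_mean[0], cfg.bw_test_mean[1]
    ) + np.array([frac * cfg.bw_test_sd * fam_misc[f][2] for f in family]) \
        + resid * cfg.bw_test_sd * rng.normal(size=n)
    bwg = np.where(genotype == "lav/lav", cfg.bwg_mean[0], cfg.bwg_mean[1]) \
        + cfg.bwg_sd * rng.normal(size=n)
    mbw = np.power(np.maximum(bw_test, 1.0), cfg.mbw_exponent)
    egg_n = np.where(genotype == "lav/lav", cfg.egg_number_mean[0], cfg.egg_number_mean[1]) \
        + cfg.egg_number_sd * rng.normal(size=n)
    egg_w = cfg.egg_weight_mean + cfg.egg_weight_sd * rng.normal(size=n)
    em = np.maximum(egg_n, 0.0) * np.maximum(egg_w, 0.0)
    em[sex == "M"] = np.nan

    # genotype shift on the feed-intake residual, centered over the cohort
    n_test_total = max(cfg.n_test_lav + cfg.n_test_wt, 1)
    shift_lav = cfg.rfi_shift * cfg.n_test_wt / n_test_total
    shift_wt = -cfg.rfi_shift * cfg.n_test_lav / n_test_total
    gshift = np.where(genotype == "lav/lav", shift_lav, shift_wt)

    fi = np.full(n, np.nan)
    for s in ("F", "M"):
        mask = sex == s
        if s == "F":
            b0, b1, b2, b3 = cfg.female_coefs
            pred = b0 + b1 * bwg[mask] + b2 * mbw[mask] + b3 * np.nan_to_num(em[mask])
            r2 = cfg.female_r2
        else:
            b0, b1, b2 = cfg.male_coefs
            pred = b0 + b1 * bwg[mask] + b2 * mbw[mask]
            r2 = cfg.male_r2
        var_sig = float(np.var(pred)) if mask.sum() > 1 else 0.0
        if var_sig < 1e-9:  # degenerate noise-free configuration
            var_sig = 0.0
        var_resid_target = var_sig * (1.0 - r2) / r2 if r2 > 0 else 0.0
        var_geno = float(np.var(gshift[mask])) if mask.sum() > 1 else 0.0
        noise_sd = float(np.sqrt(max(var_resid_target - var_geno, 0.0)))
        fam_part = np.array([frac * noise_sd * fam_misc[f][0] for f in family[mask]])
        ind_part = resid * noise_sd * rng.normal(size=int(mask.sum()))
        fi[mask] = pred + gshift[mask] + fam_part + ind_part

    temp = cfg.temp_mean_wt + np.where(genotype == "lav/lav", cfg.temp_shift, 0.0) \
        + np.array([frac * cfg.temp_sd * fam_misc[f][1] for f in family]) \
        + resid * cfg.temp_sd * rng.normal(size=n) \
        + cfg.temp_bw_slope * (bw_test - float(np.mean(cfg.bw_test_mean)))

    bw6 = np.where(genotype == "lav/lav", cfg.bw6_mean[0], cfg.bw6_mean[1]) \
        + np.array([frac * cfg.bw6_sd * fam_misc[f][3] for f in family]) \
        + resid * cfg.bw6_sd * rng.normal(size=n)
    carcass = bw6 - (cfg.carcass_offset_mean + cfg.carcass_offset_sd * rng.normal(size=n))
    pect = np.where(genotype == "lav/lav", cfg.pectoralis_mean[0], cfg.pectoralis_mean[1]) \
        + cfg.pectoralis_sd * rng.normal(size=n) + 0.02 * (carcass - float(np.mean(carcass)))
    liver = np.where(genotype == "lav/lav", cfg.liver_mean[0], cfg.liver_mean[1]) \
        + cfg.liver_sd * rng.normal(size=n) + 0.01 * (carcass - float(np.mean(carcass)))

    df["bw_test"] = bw_test
    df["BWG"] = bwg
    df["MBW"] = mbw
    df["egg_number"] = np.where(sex == "F", egg_n, np.nan)
    df["egg_weight"] = np.where(sex == "F", egg_w, np.nan)
    df["EM"] = em
    df["FI"] = fi
    df["body_temp"] = temp
    df["bw_6mo"] = bw6
    df["carcass"] = carcass
    df["pectoralis"] = pect
    df["liver"] = liver
    for col in ("bw_test", "BWG", "FI", "body_temp", "EM", "egg_number",
                "egg_weight", "bw_6mo", "carcass", "pectoralis", "liver"):
        df.loc[~df["on_test"], col] = np.nan

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        df.to_csv(os.path.join(outdir, "phenotypes.tsv"), sep="\t", index=False,
                  float_format="%.6g")
    return df
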