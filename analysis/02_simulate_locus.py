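#!/usr/bin/env python
"""Generate the synthetic locus: region, derived allele, reads, panel.

Writes the wild-type region (FASTA + GFF3 + breakpoint TSV), the derived
lavender allele with its truth painting, the two chromosome-walk reads and
the 16-amplicon screening panel with per-allele calls, all under
results/fixture/.  Every output is a pure function of --seed.
"""

import argparse
import os

from lavlocus.simulate import (
    FixtureConfig,
    lav60_events,
    make_allele_and_reads,
    make_panel_and_calls,
    make_region,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "fixture")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = FixtureConfig(seed=args.seed)
    region, seq = make_region(cfg, outdir=OUT)
    events = lav60_events(region)
    derived, reads, truth = make_allele_and_reads(region, seq, events, cfg, outdir=OUT)
    make_panel_and_calls(region, truth.painting, outdir=OUT)

    print(f"region: {region.length_bp} bp, {len(region.genes)} genes, "
          f"breakpoints {region.breakpoint_positions()}")
    print(f"derived allele: {len(derived)} bp "
          f"({region.length_bp - len(derived)} bp deleted)")
    print(f"junctions: {[j.name for j in truth.junctions]}")
    print(f"walk reads: {[(k, len(v)) for k, v in reads.items()]}")
    print(f"wrote fixture to {OUT}")


if __name__ == "__main__":
    main()
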