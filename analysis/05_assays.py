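#!/usr/bin/env python
"""Predict the molecular assays on wild-type and lavender alleles.

Three-primer genotyping (423-bp wild-type band, 630-bp lavender band),
per-gene structural consequences, and exon-pair RT-PCR outcomes.  Writes
results/assays.json.
"""

import argparse
import json
import os

from lavlocus.assays import (
    annotate_consequences,
    call_genotype,
    genotyping_bands,
    predict_rt_pcr,
)
from lavlocus.engine import identity_painting
from lavlocus.simulate import (
    FixtureConfig,
    genotyping_primers,
    lav60_events,
    make_allele_and_reads,
    make_region,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")

RT_PAIRS = {"MLPH": [(1, 2), (5, 7), (1, 7), (8, 10), (1, 10), (5, 10)],
            "PRLH": [(1, 2), (1, 3)],
            "RAB17": [(1, 4), (3, 4)]}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = FixtureConfig(seed=args.seed)
    region, seq = make_region(cfg)
    _, _, truth = make_allele_and_reads(region, seq, lav60_events(region), cfg)
    wt = identity_painting(region.length_bp)
    lav = truth.painting

    primers = genotyping_primers(region.breakpoints)
    out = {"genotyping": {}, "consequences": [], "rt_pcr": {}}
    for label, alleles in (("+/+", [wt, wt]), ("lav/+", [wt, lav]),
                           ("lav/lav", [lav, lav])):
        bands = genotyping_bands(alleles, primers)
        call = call_genotype(bands, 423, 630)
        out["genotyping"][label] = {"bands": sorted(bands.sizes), "call": call}
        print(f"genotype {label:<8s} bands {sorted(bands.sizes)} -> called {call}")

    for c in annotate_consequences(region, lav):
        out["consequences"].append(
            {"gene": c.gene, "status": c.status,
             "retained_exons": list(c.retained_exons),
             "transcript": c.transcript_prediction})
        print(f"{c.gene:<8s} {c.status:<10s} retained exons "
              f"{list(c.retained_exons)}: {c.transcript_prediction}")

    for gene_name, pairs in RT_PAIRS.items():
        res = predict_rt_pcr(region.gene(gene_name), lav, pairs)
        out["rt_pcr"][gene_name] = {f"{i}-{j}": v for (i, j), v in res.items()}
        print(f"RT-PCR {gene_name}: " + ", ".join(
            f"exons {i}-{j}: {v}" for (i, j), v in res.items()))

    os.makedirs(OUT, exist_ok=True)
    with open(os.path.join(OUT, "assays.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {os.path.join(OUT, 'assays.json')}")


if __name__ == "__main__":
    main()
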