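"""Molecular assay prediction on arbitrary alleles of the locus.

All predictions are purely structural: a primer binds iff its wild-type
footprint survives unbroken (not split by a novel junction, not deleted) in
the target allele; a primer pair yields a product iff the bound images face
each other on opposite strands within a maximum product size.  RT-PCR
outcome prediction likewise asks only whether the probed exons remain
intact and mutually unrearranged — no expression-level or splicing model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .engine import SegmentPainting
from .region import GeneModel, RegionMap

__all__ = [
    "Primer",
    "PCRProduct",
    "BandPattern",
    "GeneConsequence",
    "insilico_pcr",
    "genotyping_bands",
    "call_genotype",
    "predict_rt_pcr",
    "annotate_consequences",
]

MAX_PRODUCT_DEFAULT = 5000
SIZE_TOL_DEFAULT = 20


@dataclass(frozen=True)
class Primer:
    """A primer named by its wild-type binding footprint and strand.

    ``strand`` '+' primers extend toward increasing wild-type coordinate,
    '-' primers toward decreasing.  ``role`` records the genotyping design
    intent (generic / wt-specific / mutant-specific).
    """

    name: str
    wt_start: int
    wt_end: int
    strand: str
    role: str = "generic"

    def __post_init__(self) -> None:
        if self.wt_end - self.wt_start < 15:
            raise ValueError(f"primer {self.name}: footprint must be >= 15 bp")
        if self.strand not in ("+", "-"):
            raise ValueError(f"primer {self.name}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PCRProduct:
    fwd: str
    rev: str
    size: int


@dataclass(frozen=True)
class BandPattern:
    """Observed/predicted product sizes for one sample."""

    sizes: frozenset[int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("band sizes must be positive")


def _map_primer(painting: SegmentPainting, primer: Primer):
    """Derived-allele image of a primer, or None if split/deleted.

    Returns (derived_start, derived_end, derived_strand) with the footprint
    intact inside a single segment.
    """
    pos = 0
    for ws, we, o in painting.segments:
        ln = we - ws
        if ws <= primer.wt_start and primer.wt_end <= we:
            if o == 1:
                ds = pos + (primer.wt_start - ws)
                strand = primer.strand
            else:
                ds = pos + (we - primer.wt_end)
                strand = "-" if primer.strand == "+" else "+"
            return (ds, ds + (primer.wt_end - primer.wt_start), strand)
        pos += ln
    return None


def insilico_pcr(painting: SegmentPainting, primers: Sequence[Primer],
                 max_product: int = MAX_PRODUCT_DEFAULT) -> list[PCRProduct]:
    """Predict all products of a primer set on one allele.

    A product is emitted for every primer pair whose derived-allele images
    lie on opposite strands facing inward within ``max_product``; its size
    is the distance between the outermost primer ends on the derived
    allele.  Primers whose site is split by a junction simply fail to bind.
    """
    bound = []
    for p in primers:
        img = _map_primer(painting, p)
        if img is not None:
            bound.append((p, img))
    products = []
    for i, (p, (ps, pe, pstr)) in enumerate(bound):
        for q, (qs, qe, qstr) in bound[i + 1:]:
            if pstr == qstr:
                continue
            fwd, rev = ((p, ps, pe), (q, qs, qe)) if pstr == "+" else ((q, qs, qe), (p, ps, pe))
            fp, fs, fe = fwd
            rp, rs, re_ = rev
            if fs >= rs:  # reverse primer must lie downstream of forward
                continue
            size = re_ - fs
            if size <= max_product:
                products.append(PCRProduct(fwd=fp.name, rev=rp.name, size=size))
    return sorted(products, key=lambda pr: (pr.fwd, pr.rev, pr.size))


def genotyping_bands(paintings: Sequence[SegmentPainting], primers: Sequence[Primer],
                     max_product: int = MAX_PRODUCT_DEFAULT) -> BandPattern:
    """Union of product sizes over the (one or two) alleles of a bird."""
    sizes: set[int] = set()
    for p in paintings:
        sizes.update(pr.size for pr in insilico_pcr(p, primers, max_product))
    return BandPattern(sizes=frozenset(sizes))


def call_genotype(pattern: BandPattern, wt_size: int, lav_size: int,
                  size_tol: int = SIZE_TOL_DEFAULT) -> str:
    """Call +/+, lav/+, lav/lav or no-call from a band pattern.

    The two expected sizes must be distinguishable beyond 2 x size_tol.
    """
    if abs(wt_size - lav_size) <= 2 * size_tol:
        raise ValueError(
            f"expected sizes {wt_size} and {lav_size} overlap within 2 x {size_tol}"
        )
    has_wt = any(abs(s - wt_size) <= size_tol for s in pattern.sizes)
    has_lav = any(abs(s - lav_size) <= size_tol for s in pattern.sizes)
    if has_wt and has_lav:
        return "lav/+"
    if has_wt:
        return "+/+"
    if has_lav:
        return "lav/lav"
    return "no-call"


# ---------------------------------------------------------------------------
# Consequence annotation and RT-PCR


@dataclass(frozen=True)
class GeneConsequence:
    """Structural fate of one gene on a derived allele."""

    gene: str
    status: str  # intact | truncated | deleted | rearranged
    retained_exons: tuple[int, ...]
    transcript_prediction: str

    def __post_init__(self) -> None:
        if self.status == "deleted" and self.retained_exons:
            raise ValueError(f"{self.gene}: deleted genes retain no exons")


def _exon_segment(painting: SegmentPainting, xs: int, xe: int) -> Optional[int]:
    """Index of the painting segment fully containing [xs, xe), else None."""
    for i, (ws, we, _) in enumerate(painting.segments):
        if ws <= xs and xe <= we:
            return i
    return None


def _any_base_retained(painting: SegmentPainting, xs: int, xe: int) -> bool:
    return any(ws < xe and xs < we for ws, we, _ in painting.segments)


def annotate_consequences(region: RegionMap, painting: SegmentPainting,
                          promoter_flank: int = 200) -> list[GeneConsequence]:
    """Per-gene structural consequence of a derived allele.

    * deleted — no exon base retained;
    * truncated — some exons fully retained, others lost (fully or split);
    * rearranged — all exons retained but the gene span (plus a promoter
      flank upstream of exon 1) no longer sits in one unbroken
      co-oriented run of the derived allele;
    * intact — otherwise.
    """
    out = []
    for g in region.genes:
        retained = tuple(
            i for i, (xs, xe) in enumerate(g.exons, start=1)
            if _exon_segment(painting, xs, xe) is not None
        )
        any_base = any(_any_base_retained(painting, xs, xe) for xs, xe in g.exons)
        if not any_base:
            out.append(GeneConsequence(g.name, "deleted", (), "none"))
            continue
        if len(retained) < len(g.exons):
            pred = _truncated_prediction(g, retained)
            out.append(GeneConsequence(g.name, "truncated", retained, pred))
            continue
        s, e = g.span
        if g.strand == "+":
            s = max(0, s - promoter_flank)
        else:
            e = min(region.length_bp, e + promoter_flank)
        whole = _exon_segment(painting, s, e)
        if whole is not None:
            out.append(GeneConsequence(g.name, "intact", retained, "full-length"))
        else:
            out.append(
                GeneConsequence(g.name, "rearranged", retained,
                                "uncertain (gene structure disrupted)")
            )
    return out


def _truncated_prediction(g: GeneModel, retained: tuple[int, ...]) -> str:
    k = 0
    for i in range(1, len(g.exons) + 1):
        if i in retained:
            k = i
        else:
            break
    if k:
        return f"truncated transcript (exons 1-{k})"
    return "no productive transcript"


def predict_rt_pcr(gene: GeneModel, painting: SegmentPainting,
                   exon_pairs: Sequence[tuple[int, int]]) -> dict[tuple[int, int], str]:
    """Predict amplify/fail for exon-pair RT-PCRs on one allele.

    A pair amplifies iff both probed exons are fully retained inside one and
    the same painting segment — i.e. no novel junction or inversion falls
    between them, so the transcribed run through both exons is unchanged.
    """
    results = {}
    for i, j in exon_pairs:
        if not (1 <= i < j <= len(gene.exons)):
            raise ValueError(f"bad exon pair ({i}, {j}) for {gene.name}")
        si = _exon_segment(painting, *gene.exons[i - 1])
        sj = _exon_segment(painting, *gene.exons[j - 1])
        ok = si is not None and sj is not None and si == sj
        results[(i, j)] = "amplify" if ok else "fail"
    return results
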