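"""Wild-type coordinate frame for the quail *lavender* locus.

The locus is a ~60-kb autosomal region carrying, in order along the
chromosome, the genes MLPH, PRLH, RAB17 and LRRFIP1, plus six named
rearrangement breakpoints BP1 < BP2 < ... < BP6.  Everything downstream
(painting algebra, assay prediction, reconstruction) measures positions in
this frame.

Conventions
-----------
* All internal coordinates are 0-based, half-open ``[start, end)``.
* Position 0 is the MLPH-proximal end of the region; coordinates increase
  toward LRRFIP1.
* GFF3 input/output uses the standard 1-based inclusive convention and is
  converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_NAMES = ("MLPH", "PRLH", "RAB17", "LRRFIP1")

__all__ = [
    "GENE_NAMES",
    "GeneModel",
    "RegionMap",
    "BreakpointConstraint",
    "RegionValidationError",
    "load_region",
    "write_region",
    "locate",
    "read_fasta",
    "write_fasta",
]


def read_fasta(path: str) -> str:
    """Sequence of the single record in a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise RegionValidationError(f"{path}: expected exactly one FASTA record")
    return str(records[0].seq).upper()


def write_fasta(path: str, name: str, seq: str) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


class RegionValidationError(ValueError):
    """Raised when a region annotation violates the locus invariants."""


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single exon chain.

    ``exons`` are half-open wild-type intervals in *transcript* order: for a
    minus-strand gene exon 1 has the highest genomic coordinate.
    """

    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.name not in GENE_NAMES:
            raise RegionValidationError(
                f"unknown gene name {self.name!r}; expected one of {GENE_NAMES}"
            )
        if self.strand not in ("+", "-"):
            raise RegionValidationError(f"bad strand {self.strand!r} for {self.name}")
        if len(self.exons) < 1:
            raise RegionValidationError(f"{self.name}: at least one exon required")
        for s, e in self.exons:
            if not s < e:
                raise RegionValidationError(f"{self.name}: empty exon [{s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise RegionValidationError(f"{self.name}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise RegionValidationError(
                f"{self.name}: exons not in transcript order for strand {self.strand}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def exon_index_at(self, position: int) -> Optional[int]:
        """1-based exon index containing ``position``, or None."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= position < e:
                return i
        return None

    def intron_index_at(self, position: int) -> Optional[int]:
        """1-based intron index: intron i lies between exons i and i+1."""
        for i in range(len(self.exons) - 1):
            a, b = self.exons[i], self.exons[i + 1]
            # genomic gap between consecutive transcript exons
            lo, hi = (a[1], b[0]) if self.strand == "+" else (b[1], a[0])
            if lo <= position < hi:
                return i + 1
        return None


@dataclass(frozen=True)
class RegionMap:
    """The wild-type region: length, gene models and named breakpoints."""

    length_bp: int
    genes: tuple[GeneModel, ...]
    breakpoints: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = sorted(self.breakpoints)
        for a, b in zip(names, names[1:]):
            if not self.breakpoints[a] < self.breakpoints[b]:
                raise RegionValidationError(
                    f"breakpoints out of order: {a}={self.breakpoints[a]} "
                    f"!< {b}={self.breakpoints[b]}"
                )
        for name, pos in self.breakpoints.items():
            if not 0 <= pos <= self.length_bp:
                raise RegionValidationError(f"{name}={pos} outside [0, {self.length_bp}]")
        for g in self.genes:
            s, e = g.span
            if s < 0 or e > self.length_bp:
                raise RegionValidationError(
                    f"{g.name} span [{s}, {e}) outside region of length {self.length_bp}"
                )

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def breakpoint_positions(self) -> list[int]:
        return [self.breakpoints[k] for k in sorted(self.breakpoints)]


@dataclass(frozen=True)
class BreakpointConstraint:
    """One printed distance/ordering fact about the breakpoints.

    ``frame`` names the allele state in which the distance is measured:
    ``state1`` (wild-type), ``state2`` (after the first inversion) or
    ``state3`` (after the second inversion).  ``hard`` constraints must be
    satisfied within ``tolerance``; soft ones only contribute residuals.
    """

    kind: str  # distance | ordering
    operands: tuple[str, str]
    value: int = 0
    frame: str = "state1"
    tolerance: int = 0
    hard: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "ordering"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.kind == "distance" and self.value <= 0:
            raise ValueError("distance constraints need value > 0")


def locate(region: RegionMap, position: int):
    """Feature context of a wild-type position.

    Returns ``(gene_name, "exon", i)`` / ``(gene_name, "intron", i)`` with
    1-based indices in transcript order, or ``(None, "intergenic", None)``.
    """
    if not 0 <= position < region.length_bp:
        raise IndexError(f"position {position} outside [0, {region.length_bp})")
    for g in region.genes:
        s, e = g.span
        if s <= position < e:
            i = g.exon_index_at(position)
            if i is not None:
                return (g.name, "exon", i)
            i = g.intron_index_at(position)
            if i is not None:
                return (g.name, "intron", i)
    return (None, "intergenic", None)


# ---------------------------------------------------------------------------
# I/O


def _region_db(gff3_path: str):
    return gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )


def load_region(annotation_file: str, breakpoint_file: str) -> RegionMap:
    """Read the GFF3 gene annotation and the breakpoint TSV into a RegionMap.

    The GFF3 must contain one ``region`` feature (declaring the length), one
    ``gene`` per locus gene and its ``exon`` children.  1-based inclusive
    GFF3 coordinates are converted to 0-based half-open.
    """
    db = _region_db(annotation_file)
    length = None
    for feat in db.features_of_type("region"):
        length = feat.end  # 1-based inclusive end == length
    if length is None:
        raise RegionValidationError("GFF3 lacks a 'region' feature declaring length")

    genes = []
    for gf in db.features_of_type("gene", order_by="start"):
        name = gf.attributes.get("Name", [gf.id])[0]
        exons = []
        for ex in db.children(gf, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))
        if gf.strand == "-":
            exons = exons[::-1]
        genes.append(GeneModel(name=name, strand=gf.strand, exons=tuple(exons)))

    bp = pd.read_csv(breakpoint_file, sep="\t")
    if not {"name", "position"} <= set(bp.columns):
        raise RegionValidationError("breakpoint table needs columns 'name' and 'position'")
    breakpoints = dict(zip(bp["name"], bp["position"].astype(int)))
    return RegionMap(length_bp=int(length), genes=tuple(genes), breakpoints=breakpoints)


def write_region(region: RegionMap, annotation_file: str, breakpoint_file: str,
                 seqid: str = "LAV60") -> None:
    """Write the RegionMap back to GFF3 + breakpoint TSV (inverse of load_region)."""
    lines = ["##gff-version 3"]
    lines.append(f"{seqid}\tlavlocus\tregion\t1\t{region.length_bp}\t.\t+\t.\tID=region1")
    for g in region.genes:
        s, e = g.span
        gid = f"gene-{g.name}"
        lines.append(
            f"{seqid}\tlavlocus\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={gid};Name={g.name}"
        )
        for i, (xs, xe) in enumerate(g.exons, start=1):
            lines.append(
                f"{seqid}\tlavlocus\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                f"ID={gid}-exon{i};Parent={gid}"
            )
    with open(annotation_file, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    pd.DataFrame(
        {"name": sorted(region.breakpoints),
         "position": [region.breakpoints[k] for k in sorted(region.breakpoints)]}
    ).to_csv(breakpoint_file, sep="\t", index=False)
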