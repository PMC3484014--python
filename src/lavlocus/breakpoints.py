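"""Breakpoint evidence: tiled-amplicon screening and walk-read interpretation.

Two independent channels localize and characterize the rearrangement:

* **Screening** — a panel of PCR amplicons tiled over the wild-type region
  is scored present/absent in wild-type and mutant DNA.  Maximal runs of
  absent amplicons are candidate deleted blocks; each block yields two
  breakpoint windows bounded by the flanking working amplicons.

* **Walk reads** — junction-spanning Sanger-length reads obtained by
  chromosome walking from the flanks.  Greedy maximal exact matching
  decomposes each read into blocks that map to distinct wild-type
  locations with strands; consecutive blocks witness novel adjacencies.

Matching is exact-substring: the synthetic reads are error-free and the
generator guarantees repeat-free junction neighbourhoods, mirroring how
unambiguous Sanger matches are interpreted by eye.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "Amplicon",
    "AmpliconPanel",
    "BreakpointWindow",
    "WalkBlock",
    "WalkMatch",
    "AdjacencyObservation",
    "InconsistentReferenceError",
    "UnmappableReadError",
    "AdjacencyConflictError",
    "screen",
    "interpret_walk",
    "assemble_adjacencies",
]

MIN_ANCHOR_DEFAULT = 20
MERGE_TOL_DEFAULT = 5


class InconsistentReferenceError(ValueError):
    """An amplicon failed in the reference (wild-type) sample."""


class UnmappableReadError(ValueError):
    """No exact anchor of the required length was found for a read."""


class AdjacencyConflictError(ValueError):
    """Two observations assign contradictory strands to the same breakend."""


@dataclass(frozen=True)
class Amplicon:
    """One tiled PCR product on wild-type coordinates.

    ``fwd_pos``/``rev_pos`` are the outermost 5' ends of the two primers, so
    the product footprint is ``[fwd_pos, rev_pos)``.
    """

    name: str
    fwd_pos: int
    rev_pos: int
    primer_len: int = 20

    def __post_init__(self) -> None:
        if not self.fwd_pos < self.rev_pos:
            raise ValueError(f"amplicon {self.name}: fwd_pos must be < rev_pos")

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.fwd_pos, self.rev_pos)


@dataclass(frozen=True)
class AmpliconPanel:
    amplicons: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValueError("amplicon names must be unique")
        order = [a.fwd_pos for a in self.amplicons]
        if order != sorted(order):
            raise ValueError("amplicons must be listed in coordinate order")

    def __len__(self) -> int:
        return len(self.amplicons)


@dataclass(frozen=True)
class BreakpointWindow:
    """Wild-type interval guaranteed to contain one breakpoint of a block."""

    lo: int
    hi: int
    side: str  # proximal | distal

    @property
    def width(self) -> int:
        return self.hi - self.lo


def screen(panel: AmpliconPanel,
           wt_calls: dict[str, str],
           mut_calls: dict[str, str],
           region_length: Optional[int] = None):
    """Turn presence/absence calls into missing blocks and breakpoint windows.

    Every amplicon needs a call in both samples and must be present in the
    wild type.  Each maximal run of mutant-absent amplicons yields one
    missing block and two windows:

    * proximal: ``[end of last flanking present amplicon, end of first
      absent amplicon)`` — the proximal breakpoint cannot precede the last
      intact footprint and must touch the first failing one;
    * distal: ``[start of last absent amplicon, start of first flanking
      present amplicon)``, symmetrically.

    Blocks at the panel edge fall back to the region bounds (0 /
    ``region_length``) for the missing flank.
    """
    for a in panel.amplicons:
        for calls, which in ((wt_calls, "wild-type"), (mut_calls, "mutant")):
            if a.name not in calls or calls[a.name] not in ("present", "absent"):
                raise ValueError(f"missing or bad {which} call for amplicon {a.name}")
        if wt_calls[a.name] != "present":
            raise InconsistentReferenceError(
                f"amplicon {a.name} absent in the wild-type reference sample"
            )

    amps = panel.amplicons
    absent = [mut_calls[a.name] == "absent" for a in amps]
    blocks: list[tuple[int, int]] = []  # index ranges [i, j] inclusive
    i = 0
    while i < len(amps):
        if absent[i]:
            j = i
            while j + 1 < len(amps) and absent[j + 1]:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1

    windows: list[BreakpointWindow] = []
    for i, j in blocks:
        left_flank = amps[i - 1].rev_pos if i > 0 else 0
        right_flank = amps[j + 1].fwd_pos if j + 1 < len(amps) else (
            region_length if region_length is not None else amps[j].rev_pos
        )
        windows.append(BreakpointWindow(lo=left_flank, hi=amps[i].rev_pos, side="proximal"))
        windows.append(BreakpointWindow(lo=amps[j].fwd_pos, hi=right_flank, side="distal"))

    named_blocks = [
        ([a.name for a in amps[i:j + 1]], (amps[i].fwd_pos, amps[j].rev_pos))
        for i, j in blocks
    ]
    return named_blocks, windows


# ---------------------------------------------------------------------------
# Walk-read interpretation


@dataclass(frozen=True)
class WalkBlock:
    """One exactly-matched block of a walk read."""

    wt_start: int
    wt_end: int
    strand: int  # +1 / -1 relative to the wild-type plus strand
    query_offset: int

    @property
    def length(self) -> int:
        return self.wt_end - self.wt_start


@dataclass(frozen=True)
class WalkMatch:
    blocks: tuple[WalkBlock, ...]
    source_flank: str = ""  # up | down | ""

    def __post_init__(self) -> None:
        offs = [b.query_offset for b in self.blocks]
        if offs != sorted(offs) or len(set(offs)) != len(offs):
            raise ValueError("query offsets must be strictly increasing")

    @property
    def n_locations(self) -> int:
        return len(self.blocks)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


class _Matcher:
    """Exact matcher against one wild-type sequence, both strands."""

    def __init__(self, wt_seq: str, k: int):
        from .engine import revcomp

        self.seq = wt_seq.upper()
        self.k = k
        self.index = _kmer_index(self.seq, k)
        self._rc = revcomp

    def longest_match(self, read: str, offset: int):
        """Longest exact match of read[offset:] anchored at ``offset``.

        Returns (wt_start, wt_end, strand, length) or None.  Forward hits:
        read block equals wt[s:e].  Reverse hits: read block equals
        revcomp(wt[s:e]).
        """
        k = self.k
        seed = read[offset:offset + k]
        if len(seed) < k:
            return None
        best = None
        for s in self.index.get(seed, ()):  # forward strand
            ln = k
            while (offset + ln < len(read) and s + ln < len(self.seq)
                   and read[offset + ln] == self.seq[s + ln]):
                ln += 1
            if best is None or ln > best[3]:
                best = (s, s + ln, 1, ln)
        for s in self.index.get(self._rc(seed), ()):  # reverse strand
            # read[offset:offset+k] == revcomp(wt[s:s+k]); extend rightwards
            # in the read = leftwards on wild type.
            ln = k
            while (offset + ln < len(read) and s - 1 >= 0
                   and read[offset + ln] == self._rc(self.seq[s - 1])):
                s -= 1
                ln += 1
            if best is None or ln > best[3]:
                best = (s, s + ln, -1, ln)
        return best


def interpret_walk(read: str, wt_seq: str,
                   min_anchor: int = MIN_ANCHOR_DEFAULT,
                   merge_tol: int = MERGE_TOL_DEFAULT,
                   source_flank: str = "") -> WalkMatch:
    """Decompose a walk read into exactly-matched wild-type blocks.

    Greedy maximal exact matching from the read's 5' end: at each offset the
    longest exact match (either strand) of at least ``min_anchor`` bases is
    taken and the offset advances past it; offsets with no qualifying
    anchor advance by one base (sub-anchor stretches stay unmatched).
    Successive blocks that are wild-type-contiguous on the same strand
    (gap <= ``merge_tol`` both on the read and the reference) are merged.
    """
    if len(read) < 2 * min_anchor:
        raise ValueError(
            f"read of length {len(read)} shorter than 2 x min_anchor ({2 * min_anchor})"
        )
    read = read.upper()
    matcher = _Matcher(wt_seq, min_anchor)
    blocks: list[WalkBlock] = []
    o = 0
    while o <= len(read) - min_anchor:
        hit = matcher.longest_match(read, o)
        if hit is None:
            o += 1
            continue
        s, e, strand, ln = hit
        blocks.append(WalkBlock(wt_start=s, wt_end=e, strand=strand, query_offset=o))
        o += ln
    if not blocks:
        raise UnmappableReadError(
            f"no exact anchor of length {min_anchor} found for read of length {len(read)}"
        )
    return WalkMatch(blocks=tuple(_merge_blocks(blocks, merge_tol)), source_flank=source_flank)


def _merge_blocks(blocks: list[WalkBlock], merge_tol: int) -> list[WalkBlock]:
    out = [blocks[0]]
    for b in blocks[1:]:
        a = out[-1]
        qgap = b.query_offset - (a.query_offset + a.length)
        if a.strand == b.strand == 1 and 0 <= b.wt_start - a.wt_end <= merge_tol and qgap <= merge_tol:
            out[-1] = WalkBlock(a.wt_start, b.wt_end, 1, a.query_offset)
        elif a.strand == b.strand == -1 and 0 <= a.wt_start - b.wt_end <= merge_tol and qgap <= merge_tol:
            out[-1] = WalkBlock(b.wt_start, a.wt_end, -1, a.query_offset)
        else:
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# Adjacency assembly


@dataclass(frozen=True)
class AdjacencyObservation:
    """A strand-aware novel adjacency observed between two wild-type breakends.

    Breakends are ``(wt_position, strand)`` as in the derived-allele read
    order; ``tolerance`` is the +/- bp uncertainty on each position.
    """

    left: tuple[int, int]
    right: tuple[int, int]
    support: int = 1
    corroborated: bool = False
    tolerance: int = MERGE_TOL_DEFAULT


def _breakends_of_pair(a: WalkBlock, b: WalkBlock):
    left = (a.wt_end - 1, 1) if a.strand == 1 else (a.wt_start, -1)
    right = (b.wt_start, 1) if b.strand == 1 else (b.wt_end - 1, -1)
    return left, right


def _same_end(x: tuple[int, int], y: tuple[int, int], tol: int) -> bool:
    return x[1] == y[1] and abs(x[0] - y[0]) <= tol


def assemble_adjacencies(matches: Sequence[WalkMatch],
                         windows: Sequence[BreakpointWindow] = (),
                         tolerance: int = MERGE_TOL_DEFAULT) -> list[AdjacencyObservation]:
    """Collapse consecutive walk-block pairs into unique novel adjacencies.

    Two observations are the same adjacency when both breakends agree in
    strand and position within ``tolerance`` — directly, or with the pair
    reversed and both strands flipped (the same junction read from the other
    side).  A breakend falling inside a screening window marks the adjacency
    as corroborated.  Observations agreeing in position but not strand raise
    :class:`AdjacencyConflictError`.
    """
    if not matches:
        raise ValueError("at least one WalkMatch is required")
    obs: list[AdjacencyObservation] = []
    for m in matches:
        for a, b in zip(m.blocks, m.blocks[1:]):
            left, right = _breakends_of_pair(a, b)
            merged = False
            for i, prev in enumerate(obs):
                direct = _same_end(prev.left, left, tolerance) and _same_end(prev.right, right, tolerance)
                flipped = (
                    _same_end(prev.left, (right[0], -right[1]), tolerance)
                    and _same_end(prev.right, (left[0], -left[1]), tolerance)
                )
                if direct or flipped:
                    obs[i] = AdjacencyObservation(
                        prev.left, prev.right, prev.support + 1, prev.corroborated, tolerance
                    )
                    merged = True
                    break
                pos_only = (
                    abs(prev.left[0] - left[0]) <= tolerance
                    and abs(prev.right[0] - right[0]) <= tolerance
                )
                if pos_only and not direct:
                    raise AdjacencyConflictError(
                        f"conflicting strands for adjacency near "
                        f"{prev.left[0]}/{prev.right[0]}: {prev} vs ({left}, {right})"
                    )
            if not merged:
                obs.append(AdjacencyObservation(left, right, 1, False, tolerance))
    out = []
    for o in obs:
        corr = any(w.lo <= p < w.hi for w in windows for p, _ in (o.left, o.right))
        out.append(AdjacencyObservation(o.left, o.right, o.support, corr, o.tolerance))
    return out
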