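"""Segment-painting algebra for ordered inversion/deletion rearrangements.

A derived allele is represented as an ordered mosaic of strand-signed
wild-type segments (a *painting*).  Applying an inversion reverses segment
order and flips orientations inside the event interval; a deletion removes
it.  Because every segment remembers its wild-type interval, exact liftover
between the derived allele and the wild-type frame is available at any
point, and every wild-type sub-segment bounded by an event endpoint can be
tracked through the full scenario (its *fate*): which events touched it,
whether it survived, and where it landed.

Orientation convention: ``-`` means the segment reads as the reverse
complement of the wild-type plus strand.  Events are given in
*current-allele* coordinates and applied sequentially; helpers anchor event
endpoints on named wild-type breakpoints when those positions still exist
in the current state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Event",
    "Junction",
    "SegmentFate",
    "SegmentPainting",
    "identity_painting",
    "apply_event",
    "apply_scenario",
    "lift_over",
    "inverse_lift",
    "render_sequence",
    "revcomp",
]

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Event:
    """One inversion or deletion over ``[start, end)`` of the current allele."""

    kind: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "deletion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad event interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# A segment is (wt_start, wt_end, orient) with orient in {+1, -1}.
Segment = tuple[int, int, int]


def _canonical(segments: Iterable[Segment]) -> tuple[Segment, ...]:
    """Drop empty segments and merge wild-type-contiguous equal-orientation runs."""
    out: list[Segment] = []
    for ws, we, o in segments:
        if we <= ws:
            continue
        if out:
            ps, pe, po = out[-1]
            if po == o == 1 and pe == ws:
                out[-1] = (ps, we, o)
                continue
            if po == o == -1 and ps == we:
                out[-1] = (ws, pe, o)
                continue
        out.append((ws, we, o))
    return tuple(out)


@dataclass(frozen=True)
class SegmentPainting:
    """Ordered, canonical mosaic of strand-signed wild-type segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", _canonical(self.segments))

    @property
    def total_length(self) -> int:
        return sum(we - ws for ws, we, _ in self.segments)

    def boundaries(self) -> list[int]:
        """Derived-coordinate boundaries of the canonical segments (incl. 0, L)."""
        pos, out = 0, [0]
        for ws, we, _ in self.segments:
            pos += we - ws
            out.append(pos)
        return out

    def retained_wt_intervals(self) -> list[tuple[int, int]]:
        return sorted((ws, we) for ws, we, _ in self.segments)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"segments": [[ws, we, "+" if o == 1 else "-"] for ws, we, o in self.segments]}
        )

    @classmethod
    def from_json(cls, text: str) -> "SegmentPainting":
        data = json.loads(text)
        return cls(
            tuple(
                (int(ws), int(we), 1 if o == "+" else -1)
                for ws, we, o in data["segments"]
            )
        )

    def to_table(self):
        """BED-like rows (wt_start, wt_end, orientation, derived_start)."""
        import pandas as pd

        rows, pos = [], 0
        for ws, we, o in self.segments:
            rows.append((ws, we, "+" if o == 1 else "-", pos))
            pos += we - ws
        return pd.DataFrame(rows, columns=["wt_start", "wt_end", "orientation", "derived_start"])


def identity_painting(length_bp: int) -> SegmentPainting:
    return SegmentPainting(((0, length_bp, 1),))


# ---------------------------------------------------------------------------
# Breakends and junctions


@dataclass(frozen=True)
class Junction:
    """A novel adjacency between two wild-type breakends in the derived allele.

    Each breakend is ``(wt_position, strand)`` where the position is the
    wild-type base immediately flanking the junction on that side and the
    strand is the orientation in which that flank is read.
    """

    left: tuple[int, int]
    right: tuple[int, int]
    derived_pos: int
    name: str = ""

    @property
    def is_novel(self) -> bool:
        (lp, lo), (rp, ro) = self.left, self.right
        return not (lo == ro and ((lo == 1 and rp == lp + 1) or (lo == -1 and rp == lp - 1)))


def _segment_ends(seg: Segment) -> tuple[tuple[int, int], tuple[int, int]]:
    """(first-base, last-base) breakends of a segment in derived read order."""
    ws, we, o = seg
    if o == 1:
        return (ws, 1), (we - 1, 1)
    return (we - 1, -1), (ws, -1)


def junctions_of(painting: SegmentPainting, name_prefix: str = "R") -> list[Junction]:
    """Novel junctions at canonical segment boundaries, in derived order.

    After canonicalization every internal boundary is a novel junction (a
    wild-type-contiguous boundary would have been merged away).  Junctions
    are numbered R1..Rn in ascending derived coordinate.
    """
    segs = painting.segments
    out = []
    pos = 0
    for i in range(len(segs) - 1):
        pos += segs[i][1] - segs[i][0]
        left = _segment_ends(segs[i])[1]
        right = _segment_ends(segs[i + 1])[0]
        out.append(Junction(left=left, right=right, derived_pos=pos))
    return [
        Junction(j.left, j.right, j.derived_pos, name=f"{name_prefix}{i + 1}")
        for i, j in enumerate(out)
    ]


# ---------------------------------------------------------------------------
# Event application


def apply_event(painting: SegmentPainting, event: Event) -> SegmentPainting:
    """Apply one inversion/deletion given in current-allele coordinates."""
    L = painting.total_length
    if event.end > L:
        raise IndexError(
            f"event interval [{event.start}, {event.end}) exceeds allele length {L}"
        )
    pre, mid, post = _split(painting.segments, event.start, event.end)
    if event.kind == "inversion":
        mid = tuple((ws, we, -o) for ws, we, o in reversed(mid))
        return SegmentPainting(pre + mid + post)
    return SegmentPainting(pre + post)


def _split(segments: Sequence[Segment], a: int, b: int):
    """Split segments at derived coordinates a <= b; return (pre, mid, post)."""
    pre: list[Segment] = []
    mid: list[Segment] = []
    post: list[Segment] = []
    pos = 0
    for seg in segments:
        ws, we, o = seg
        ln = we - ws
        s0, s1 = pos, pos + ln
        for lo, hi, sink in ((s0, min(s1, a), pre),
                             (max(s0, a), min(s1, b), mid),
                             (max(s0, b), s1, post)):
            if hi > lo:
                sink.append(_subseg(seg, lo - s0, hi - s0))
        pos = s1
    return tuple(pre), tuple(mid), tuple(post)


def _subseg(seg: Segment, off0: int, off1: int) -> Segment:
    """Sub-segment covering derived offsets [off0, off1) of ``seg``."""
    ws, we, o = seg
    if o == 1:
        return (ws + off0, ws + off1, 1)
    return (we - off1, we - off0, -1)


# ---------------------------------------------------------------------------
# Scenario application with fate tracking


@dataclass(frozen=True)
class SegmentFate:
    """Fate of one wild-type sub-segment across a scenario.

    ``hits`` has one flag per event: True if the event interval covered the
    segment in the state where the event applied.  ``status`` is
    ``retained+``/``retained-``/``deleted``; retained segments also report
    their final derived interval.
    """

    wt_start: int
    wt_end: int
    hits: tuple[bool, ...]
    status: str
    derived_start: Optional[int] = None
    derived_end: Optional[int] = None

    @property
    def length(self) -> int:
        return self.wt_end - self.wt_start


@dataclass
class ScenarioResult:
    painting: SegmentPainting
    junctions: list[Junction]
    fates: list[SegmentFate]
    trajectory: list[SegmentPainting] = field(default_factory=list)


def apply_scenario(region_length: int, events: Sequence[Event],
                   painting: Optional[SegmentPainting] = None) -> ScenarioResult:
    """Apply ordered events to the wild-type allele, tracking fates.

    Fate tracking maintains an annotated painting whose segments carry
    per-event hit flags; deleted pieces are moved to a graveyard.  The final
    atomic partition of the wild type is exactly the partition induced by
    the images of all event endpoints.
    """
    if painting is None:
        painting = identity_painting(region_length)
    n = len(events)
    live: list[tuple[Segment, list[bool]]] = [(s, [False] * n) for s in painting.segments]
    dead: list[tuple[Segment, list[bool]]] = []
    trajectory = [painting]
    current = painting
    for idx, ev in enumerate(events):
        if ev.end > current.total_length:
            raise IndexError(
                f"event {idx} ({ev.kind} [{ev.start}, {ev.end})) exceeds "
                f"allele length {current.total_length}"
            )
        live = _apply_annotated(live, ev, idx, dead)
        current = SegmentPainting(tuple(s for s, _ in live))
        trajectory.append(current)

    fates = []
    pos = 0
    for (ws, we, o), hits in live:
        fates.append(
            SegmentFate(
                wt_start=ws, wt_end=we, hits=tuple(hits),
                status="retained+" if o == 1 else "retained-",
                derived_start=pos, derived_end=pos + (we - ws),
            )
        )
        pos += we - ws
    for (ws, we, _), hits in dead:
        fates.append(SegmentFate(wt_start=ws, wt_end=we, hits=tuple(hits), status="deleted"))
    fates.sort(key=lambda f: f.wt_start)
    return ScenarioResult(
        painting=current,
        junctions=junctions_of(current),
        fates=fates,
        trajectory=trajectory,
    )


def _apply_annotated(live, ev: Event, idx: int, dead):
    out = []
    mid = []
    pos = 0
    for seg, hits in live:
        ws, we, o = seg
        ln = we - ws
        s0, s1 = pos, pos + ln
        parts = []
        for lo, hi in ((s0, min(s1, ev.start)),
                       (max(s0, ev.start), min(s1, ev.end)),
                       (max(s0, ev.end), s1)):
            if hi > lo:
                parts.append((lo, hi, _subseg(seg, lo - s0, hi - s0)))
        for lo, hi, sub in parts:
            inside = lo >= ev.start and hi <= ev.end
            newhits = list(hits)
            if inside:
                newhits[idx] = True
            if inside:
                mid.append((sub, newhits, lo))
            else:
                out.append((lo, sub, newhits))
        pos = s1
    if ev.kind == "inversion":
        mid = [((sub[0], sub[1], -sub[2]), h, ev.start + ev.end - (lo + (sub[1] - sub[0])))
               for sub, h, lo in reversed([(s, h, lo) for s, h, lo in mid])]
        merged = out + [(lo, sub, h) for sub, h, lo in mid]
    else:
        for sub, h, _ in mid:
            dead.append((sub, h))
        # shift positions after the deletion
        merged = []
        for lo, sub, h in out:
            merged.append((lo if lo < ev.start else lo - ev.length, sub, h))
    merged.sort(key=lambda t: t[0])
    return [(sub, h) for _, sub, h in merged]


# ---------------------------------------------------------------------------
# Liftover


def lift_over(painting: SegmentPainting, derived_position: int) -> tuple[int, int]:
    """Map a derived-allele position to (wt_position, strand)."""
    if not 0 <= derived_position < painting.total_length:
        raise IndexError(
            f"derived position {derived_position} outside [0, {painting.total_length})"
        )
    pos = 0
    for ws, we, o in painting.segments:
        ln = we - ws
        if pos <= derived_position < pos + ln:
            off = derived_position - pos
            return (ws + off, 1) if o == 1 else (we - 1 - off, -1)
        pos += ln
    raise AssertionError("unreachable")


def inverse_lift(painting: SegmentPainting, wt_position: int) -> Optional[tuple[int, int]]:
    """Map a wild-type position into the derived allele, or None if deleted."""
    pos = 0
    for ws, we, o in painting.segments:
        ln = we - ws
        if ws <= wt_position < we:
            off = wt_position - ws
            return (pos + off, 1) if o == 1 else (pos + (ln - 1 - off), -1)
        pos += ln
    return None


# ---------------------------------------------------------------------------
# Sequence rendering


def render_sequence(wt_sequence: str, painting: SegmentPainting) -> str:
    """Materialize the derived-allele sequence from the wild-type sequence."""
    need = max((we for _, we, _ in painting.segments), default=0)
    if need > len(wt_sequence):
        raise ValueError(
            f"wild-type sequence of length {len(wt_sequence)} shorter than "
            f"painting extent {need}"
        )
    parts = []
    for ws, we, o in painting.segments:
        chunk = wt_sequence[ws:we]
        parts.append(chunk if o == 1 else revcomp(chunk))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Breakpoint-anchored event helpers


def anchored_events(region_length: int,
                    specs: Sequence[tuple[str, str, str]],
                    breakpoints: dict[str, int]) -> list[Event]:
    """Resolve events whose endpoints are named wild-type breakpoints.

    Each spec is ``(kind, left_name, right_name)``; the endpoints are the
    *current-state images* of the named wild-type boundary coordinates, so a
    later event may legally cut at a breakpoint that earlier inversions have
    displaced.  Raises if an endpoint has been deleted.
    """
    painting = identity_painting(region_length)
    events = []
    for kind, a_name, b_name in specs:
        pts = []
        for nm in (a_name, b_name):
            wt = breakpoints[nm]
            img = _boundary_image(painting, wt)
            if img is None:
                raise ValueError(f"breakpoint {nm} no longer exists when event applies")
            pts.append(img)
        lo, hi = min(pts), max(pts)
        ev = Event(kind=kind, start=lo, end=hi, label=f"{kind} {a_name}-{b_name}")
        events.append(ev)
        painting = apply_event(painting, ev)
    return events


def _boundary_image(painting: SegmentPainting, wt_boundary: int) -> Optional[int]:
    """Derived-coordinate image of a wild-type *boundary* (cut point)."""
    pos = 0
    for ws, we, o in painting.segments:
        ln = we - ws
        if ws <= wt_boundary <= we:
            off = wt_boundary - ws
            cand = pos + off if o == 1 else pos + (ln - off)
            if 0 <= cand <= painting.total_length:
                return cand
        pos += ln
    return None


def boundary_images(painting: SegmentPainting, wt_boundary: int) -> list[int]:
    """All derived cut-point images of a wild-type boundary coordinate."""
    out = []
    pos = 0
    for ws, we, o in painting.segments:
        ln = we - ws
        if ws <= wt_boundary <= we:
            out.append(pos + (wt_boundary - ws) if o == 1 else pos + (we - wt_boundary))
        pos += ln
    return sorted(set(c for c in out if 0 <= c <= painting.total_length))
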