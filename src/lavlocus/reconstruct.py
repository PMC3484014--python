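"""Parsimonious reconstruction of ordered inversion/deletion scenarios.

Two solvers live here:

* :func:`enumerate_scenarios` — breadth-first search over event sequences
  from the wild-type painting to a target painting.  Candidate event
  endpoints are restricted to the images, in each intermediate state, of
  the wild-type cut coordinates that bound the target's segments: any
  minimal scenario's cuts must either surface as target junction flanks or
  be consumed by a later deletion bounded by such flanks, so this
  restriction preserves completeness at minimal depth while keeping the
  search finite.  States are deduplicated by canonical painting; all
  minimal-length scenarios (as distinct painting trajectories) are
  returned.

* :func:`solve_coordinates` — least-absolute-residual placement of the
  named breakpoints given printed distance constraints, each measured in a
  declared allele state (frame).  Distances are affine functions of the
  breakpoint positions within a fixed combinatorial shape; the solver
  probes the affine coefficients numerically through the forward engine,
  solves the resulting LP (scipy linprog), and verifies the rounded
  integer solution by re-simulating every constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .engine import (
    Event,
    SegmentPainting,
    _canonical,
    _split,
    apply_event,
    apply_scenario,
    boundary_images,
    identity_painting,
)
from .region import BreakpointConstraint, RegionMap

__all__ = [
    "Scenario",
    "CoordinateSolution",
    "enumerate_scenarios",
    "solve_coordinates",
    "report_scenario",
]


@dataclass(frozen=True)
class Scenario:
    """An ordered event list reproducing a target painting from wild type."""

    events: tuple[Event, ...]
    trajectory: tuple[SegmentPainting, ...] = ()

    @property
    def score(self) -> int:
        return len(self.events)


@dataclass
class EnumerationResult:
    scenarios: list[Scenario]
    minimal_length: Optional[int]
    bound_exceeded: bool
    states_explored: int


# ---------------------------------------------------------------------------
# BFS enumeration


def _fast_apply(segs: tuple, kind: str, a: int, b: int) -> tuple:
    pre, mid, post = _split(segs, a, b)
    if kind == "inversion":
        mid = tuple((ws, we, -o) for ws, we, o in reversed(mid))
        return _canonical(pre + mid + post)
    return _canonical(pre + post)


def _candidate_cuts(segs: tuple, wt_cuts: Sequence[int]) -> list[int]:
    painting = SegmentPainting(segs)
    out: set[int] = set()
    for w in wt_cuts:
        out.update(boundary_images(painting, w))
    return sorted(out)


def _length(segs: tuple) -> int:
    return sum(we - ws for ws, we, _ in segs)


def enumerate_scenarios(region: "RegionMap | int",
                        target: SegmentPainting,
                        max_events: int = 3) -> EnumerationResult:
    """Return ALL minimal ordered scenarios producing ``target`` from wild type.

    Searches breadth-first up to ``max_events`` (bounded at 5).  If no
    scenario of length <= max_events exists the result is empty with
    ``bound_exceeded`` set.
    """
    if max_events > 5:
        raise ValueError("max_events must be <= 5")
    region_length = region if isinstance(region, int) else region.length_bp
    start = identity_painting(region_length).segments
    goal = target.segments
    target_len = _length(goal)

    wt_cuts = sorted({c for ws, we, _ in goal for c in (ws, we)} | {0, region_length})

    if start == goal:
        return EnumerationResult(
            [Scenario(events=(), trajectory=(SegmentPainting(start),))], 0, False, 1
        )

    # parents[depth][state] = list of (prev_state, move)
    parents: list[dict] = [dict() for _ in range(max_events + 1)]
    parents[0][start] = []
    frontier = {start}
    explored = 1
    for depth in range(1, max_events + 1):
        nxt: dict[tuple, list] = {}
        hits: dict[tuple, list] = {}
        for state in frontier:
            cur_len = _length(state)
            cuts = _candidate_cuts(state, wt_cuts)
            for i, a in enumerate(cuts):
                for b in cuts[i + 1:]:
                    for kind in ("inversion", "deletion"):
                        if kind == "deletion" and cur_len - (b - a) < target_len:
                            continue
                        if kind == "inversion" and cur_len != target_len and depth == max_events:
                            continue  # cannot fix length on the last move
                        new = _fast_apply(state, kind, a, b)
                        if new == state:
                            continue
                        explored += 1
                        sink = hits if new == goal else nxt
                        sink.setdefault(new, []).append((state, (kind, a, b)))
        if hits:
            scenarios = _collect_paths(parents, hits, depth, start)
            return EnumerationResult(scenarios, depth, False, explored)
        for st, par in nxt.items():
            parents[depth][st] = par
        frontier = set(nxt)
        if not frontier:
            break
    return EnumerationResult([], None, True, explored)


def _collect_paths(parents, hits, depth, start, limit: int = 10000) -> list[Scenario]:
    scenarios = []

    def walk(state, d):
        """Yield move lists from ``start`` to ``state`` at depth d."""
        if d == 0:
            yield []
            return
        table = hits if d == depth else parents[d]
        for prev, move in table.get(state, []):
            for prefix in walk(prev, d - 1):
                yield prefix + [move]

    goal = next(iter(hits))
    for moves in walk(goal, depth):
        events = tuple(Event(kind=k, start=a, end=b) for k, a, b in moves)
        cur = SegmentPainting(start)
        traj = [cur]
        for ev in events:
            cur = apply_event(cur, ev)
            traj.append(cur)
        scenarios.append(Scenario(events=events, trajectory=tuple(traj)))
        if len(scenarios) >= limit:
            break
    # dedupe identical trajectories
    seen, out = set(), []
    for sc in scenarios:
        key = tuple(p.segments for p in sc.trajectory)
        if key not in seen:
            seen.add(key)
            out.append(sc)
    return out


# ---------------------------------------------------------------------------
# Coordinate solving


@dataclass(frozen=True)
class SymbolicEvent:
    """An event whose endpoints are named breakpoints, resolved per state."""

    kind: str
    left: str
    right: str


@dataclass
class CoordinateSolution:
    positions: dict[str, int]
    residuals: dict[str, float]
    frame_mode: str
    feasible: bool
    conflict: list[str] = field(default_factory=list)
    frames_tried: list[str] = field(default_factory=list)


def _state_paintings(events: Sequence[SymbolicEvent], positions: dict[str, int],
                     region_length: int) -> list[SegmentPainting]:
    """Paintings of state1..state{n+1} for a numeric assignment."""
    from .engine import anchored_events

    evs = anchored_events(
        region_length, [(e.kind, e.left, e.right) for e in events], positions
    )
    states = [identity_painting(region_length)]
    for ev in evs:
        states.append(apply_event(states[-1], ev))
    return states


def _measure(constraint: BreakpointConstraint, states, positions,
             frame_mode: str) -> Optional[float]:
    """Measured distance for one constraint under a frame interpretation."""
    frame = "state1" if frame_mode == "wild-type" else constraint.frame
    k = int(frame.removeprefix("state")) - 1
    painting = states[min(k, len(states) - 1)]
    imgs = []
    for name in constraint.operands:
        pos = positions.get(name)
        if pos is None:
            raise KeyError(f"unknown operand {name!r}")
        cand = boundary_images(painting, pos)
        if not cand:
            return None  # operand deleted in this frame
        imgs.append(cand)
    # distance between closest image pair (operands can have two images each)
    return float(min(abs(a - b) for a in imgs[0] for b in imgs[1]))


def solve_coordinates(constraints: Sequence[BreakpointConstraint],
                      events: Sequence[SymbolicEvent],
                      names: Sequence[str] = ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6"),
                      region_length: int = 70000,
                      min_position: int = 1000,
                      fixed: Optional[dict[str, int]] = None) -> CoordinateSolution:
    """Place the named breakpoints to satisfy the printed distance constraints.

    Hard constraints must hold within their tolerances; soft constraints
    contribute to the minimized total absolute residual.  Ties are broken
    toward the smallest distal breakpoint.  On an infeasible hard set an
    infeasibility report (not an exception) names a minimal conflicting
    subset found by a deletion filter.
    """
    fixed = dict(fixed or {})
    frames = ["as-given", "wild-type"]
    last = None
    for frame_mode in frames:
        sol = _solve_one_frame(
            list(constraints), list(events), list(names), region_length,
            min_position, fixed, frame_mode
        )
        sol.frames_tried = frames[: frames.index(frame_mode) + 1]
        if sol.feasible:
            return sol
        last = sol
    return last


def _base_guess(names, region_length, min_position, fixed):
    n = len(names)
    span = region_length - min_position - 1
    guess = {
        nm: int(min_position + (i + 1) * span / (n + 1)) for i, nm in enumerate(names)
    }
    guess.update(fixed)
    return guess


def _solve_one_frame(constraints, events, names, region_length, min_position,
                     fixed, frame_mode) -> CoordinateSolution:
    dist_cons = [c for c in constraints if c.kind == "distance"]
    x0 = _base_guess(names, region_length, min_position, fixed)

    for _ in range(6):  # iterate probe -> LP until the shape is stable
        states = _state_paintings(events, x0, region_length)
        d0, coeffs, droppable = [], [], []
        for c in dist_cons:
            v = _measure(c, states, x0, frame_mode)
            if v is None:
                if c.hard:
                    return CoordinateSolution(
                        positions=dict(x0), residuals={}, frame_mode=frame_mode,
                        feasible=False,
                        conflict=[c.label or f"{c.operands} operand deleted in {c.frame}"],
                    )
                droppable.append(c)
                continue
            row = []
            for nm in names:
                xp = dict(x0)
                xp[nm] = x0[nm] + 1
                sp = _state_paintings(events, xp, region_length)
                vp = _measure(c, sp, xp, frame_mode)
                row.append((vp - v) if vp is not None else 0.0)
            d0.append(v)
            coeffs.append(row)
        use_cons = [c for c in dist_cons if c not in droppable]

        sol = _lp_solve(use_cons, d0, coeffs, names, x0, region_length,
                        min_position, fixed)
        if sol is None:
            # infeasible: deletion filter over hard constraints
            conflict = _conflict_subset(use_cons, d0, coeffs, names, x0,
                                        region_length, min_position, fixed)
            return CoordinateSolution(
                positions=dict(x0), residuals={}, frame_mode=frame_mode,
                feasible=False, conflict=conflict,
            )
        x1 = sol
        if x1 == x0:
            break
        x0 = x1

    # verify by forward simulation
    states = _state_paintings(events, x0, region_length)
    residuals, ok = {}, True
    for c in dist_cons:
        v = _measure(c, states, x0, frame_mode)
        label = c.label or f"{c.operands[0]}-{c.operands[1]}@{c.frame}"
        if v is None:
            residuals[label] = float("inf")
            ok = ok and not c.hard
            continue
        residuals[label] = v - c.value
        if c.hard and abs(v - c.value) > c.tolerance:
            ok = False
    return CoordinateSolution(
        positions=dict(x0), residuals=residuals, frame_mode=frame_mode, feasible=ok
    )


HARD_WEIGHT = 1.0
SOFT_WEIGHT = 1e-4  # printed-precision residuals dominate two-sig-fig ones
TIE_WEIGHT = 1e-7


def _lp_solve(cons, d0, coeffs, names, x0, region_length, min_position, fixed,
              drop: Optional[set] = None):
    """LP: minimize precision-weighted |residuals|, tie-break smallest BP6.

    Every constraint gets a residual-magnitude variable in the objective;
    hard constraints additionally carry a tolerance box.  Hard residuals are
    weighted so that no feasible trade against soft constraints can move a
    precisely printed length off its exact value.
    """
    drop = drop or set()
    idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    active = [k for k in range(len(cons)) if k not in drop]
    nv = n + len(active)  # positions + one residual magnitude per constraint
    cost = np.zeros(nv)
    cost[idx[names[-1]]] = TIE_WEIGHT  # ties -> smallest distal breakpoint
    for j, k in enumerate(active):
        cost[n + j] = HARD_WEIGHT if cons[k].hard else SOFT_WEIGHT

    A_ub, b_ub = [], []
    # affine model: d(x) ~= d0 + coeffs . (x - x0)
    for j, k in enumerate(active):
        c = cons[k]
        base = d0[k] - sum(coeffs[k][i] * x0[nm] for i, nm in enumerate(names))
        row = np.zeros(nv)
        for i in range(n):
            row[i] = coeffs[k][i]
        up, lo = np.array(row), -np.array(row)
        up[n + j] = -1.0
        lo[n + j] = -1.0
        A_ub.append(up); b_ub.append(c.value - base)
        A_ub.append(lo); b_ub.append(-(c.value - base))
        if c.hard:
            hup, hlo = np.array(row), -np.array(row)
            hup[n + j] = 0.0
            hlo[n + j] = 0.0
            A_ub.append(hup); b_ub.append(c.value + c.tolerance - base)
            A_ub.append(hlo); b_ub.append(-(c.value - c.tolerance) + base)
    # ordering
    for i in range(n - 1):
        row = np.zeros(nv)
        row[i] = 1.0
        row[i + 1] = -1.0
        A_ub.append(row); b_ub.append(-1.0)

    bounds = []
    for i, nm in enumerate(names):
        if nm in fixed:
            bounds.append((fixed[nm], fixed[nm]))
        else:
            bounds.append((min_position, region_length - 1))
    bounds += [(0, None)] * len(active)

    res = linprog(cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs")
    if not res.success:
        return None
    return {nm: int(round(res.x[i])) for i, nm in enumerate(names)}


def _conflict_subset(cons, d0, coeffs, names, x0, region_length, min_position,
                     fixed) -> list[str]:
    """Deletion filter: drop constraints one at a time while still infeasible."""
    hard_idx = [k for k, c in enumerate(cons) if c.hard]
    active = set(hard_idx)
    for k in list(hard_idx):
        trial_drop = set(i for i in range(len(cons)) if i not in (active - {k}))
        if _lp_solve(cons, d0, coeffs, names, x0, region_length, min_position,
                     fixed, drop=trial_drop) is None:
            active.discard(k)
    return [cons[k].label or f"{cons[k].operands}" for k in sorted(active)]


# ---------------------------------------------------------------------------
# Reporting


def report_scenario(scenario: Scenario, region: RegionMap) -> dict:
    """Figure-style per-step report of a scenario on an annotated region.

    Each step lists the event, its interval in the current allele and the
    wild-type content it covers, and the genes/exons affected.
    """
    result = apply_scenario(region.length_bp, list(scenario.events))
    steps = []
    for i, ev in enumerate(scenario.events):
        before = result.trajectory[i]
        _, mid, _ = _split(before.segments, ev.start, ev.end)
        wt_content = sorted((ws, we) for ws, we, _ in mid)
        affected = _affected_features(region, wt_content, ev.kind)
        steps.append(
            {
                "step": i + 1,
                "kind": ev.kind,
                "interval_current": [ev.start, ev.end],
                "length_bp": ev.length,
                "wt_content": [[a, b] for a, b in wt_content],
                "affected": affected,
            }
        )
    return {"n_events": len(scenario.events), "steps": steps}


def _affected_features(region: RegionMap, wt_intervals, kind: str) -> list[str]:
    notes = []
    for g in region.genes:
        touched = []
        for i, (xs, xe) in enumerate(g.exons, start=1):
            for a, b in wt_intervals:
                if xs < b and a < xe:
                    touched.append(i)
                    break
        if not touched:
            continue
        verb = "removed" if kind == "deletion" else "inverted"
        if len(touched) == len(g.exons):
            notes.append(f"{g.name}: all exons {verb}")
        else:
            notes.append(f"{g.name}: exons {touched} {verb}")
    return notes


def format_report(report: dict) -> str:
    lines = [f"reconstruction: {report['n_events']} events"]
    for s in report["steps"]:
        lines.append(
            f"  step {s['step']}: {s['kind']} [{s['interval_current'][0]}, "
            f"{s['interval_current'][1]}) ({s['length_bp']} bp)"
        )
        for a in s["affected"]:
            lines.append(f"    - {a}")
    return "\n".join(lines)
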