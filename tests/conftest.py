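"""Shared fixtures: the LAV60 bundle and random-scenario generation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from lavlocus.engine import Event, SegmentPainting, apply_event, identity_painting
from lavlocus.simulate import (
    FixtureConfig,
    lav60_events,
    make_allele_and_reads,
    make_panel_and_calls,
    make_region,
)


@dataclass
class Lav60Bundle:
    config: FixtureConfig
    region: object
    wt_seq: str
    events: list
    derived_seq: str
    reads: dict
    truth: object
    panel: object
    wt_calls: dict
    mut_calls: dict


@pytest.fixture(scope="session")
def lav60() -> Lav60Bundle:
    cfg = FixtureConfig(seed=0)
    region, seq = make_region(cfg)
    events = lav60_events(region)
    derived, reads, truth = make_allele_and_reads(region, seq, events, cfg)
    panel, wt_calls, mut_calls = make_panel_and_calls(region, truth.painting)
    return Lav60Bundle(cfg, region, seq, events, derived, reads, truth,
                       panel, wt_calls, mut_calls)


def random_scenario(rng: np.random.Generator,
                    min_len: int = 3000, max_len: int = 8000,
                    max_events: int = 3, min_sep: int = 500):
    """Random region length + 1..max_events ordered events + final painting.

    Event endpoints keep ``min_sep`` bp separation; deletions never shrink
    the allele below 1.5 kb.
    """
    L = int(rng.integers(min_len, max_len + 1))
    n = int(rng.integers(1, max_events + 1))
    events: list[Event] = []
    cur: SegmentPainting = identity_painting(L)
    for _ in range(n):
        for _attempt in range(50):
            m = cur.total_length
            if m < 3 * min_sep:
                break
            a = int(rng.integers(0, m - min_sep))
            b = int(rng.integers(a + min_sep, min(a + 4000, m) + 1))
            kind = "inversion" if rng.random() < 0.6 else "deletion"
            if kind == "deletion" and m - (b - a) < 1500:
                continue
            nxt = apply_event(cur, Event(kind, a, b))
            if nxt.segments != cur.segments:
                events.append(Event(kind, a, b))
                cur = nxt
                break
    return L, events, cur


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
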