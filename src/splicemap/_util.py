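"""Shared numeric helpers (coordinate gaps, seeded RNG streams)."""

from __future__ import annotations

import numpy as np


def gap_distance(pos: np.ndarray, span_start: float, span_end: float) -> np.ndarray:
    """Distance in bp from point positions to an inclusive interval.

    0 when the position lies inside [span_start, span_end]; otherwise the gap
    to the nearer span end. All coordinates 1-based inclusive.
    """
    pos = np.asarray(pos)
    return np.where(
        pos < span_start,
        span_start - pos,
        np.where(pos > span_end, pos - span_end, 0),
    )


def min_gap_to_events(pos: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """Per-position minimum gap distance to any of a set of spans.

    spans: (n_events, 2) array of [span_start, span_end]. Computed in
    chunks to bound memory on large panels.
    """
    pos = np.asarray(pos, dtype=np.int64)
    if len(spans) == 0:
        return np.full(len(pos), np.iinfo(np.int64).max)
    starts = spans[:, 0][None, :]
    ends = spans[:, 1][None, :]
    out = np.empty(len(pos), dtype=np.int64)
    chunk = max(1, 2_000_000 // max(1, spans.shape[0]))
    for lo in range(0, len(pos), chunk):
        p = pos[lo : lo + chunk, None]
        gap = np.where(p < starts, starts - p, np.where(p > ends, p - ends, 0))
        out[lo : lo + chunk] = gap.min(axis=1)
    return out


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically split one seed into n independent RNG streams."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
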