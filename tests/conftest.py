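"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the vectorised code paths of the package:
bout boundaries are found by a plain interval scan, the rank-sum p-value by
full enumeration of rank assignments, and the AUC by the all-pairs
comparison.  They are slow and simple on purpose.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from gaitwatch.types import DAY_SECONDS, EventStream


# --------------------------------------------------------------------------
# stream construction helpers


def make_stream(posture_rows, stride_rows, cow_id="cow", day=1) -> EventStream:
    posture = pd.DataFrame(posture_rows, columns=["start_s", "end_s", "state"])
    strides = pd.DataFrame(stride_rows,
                           columns=["start_s", "duration_ms", "distance_cm"])
    return EventStream(cow_id=cow_id, day=day, posture=posture, strides=strides)


def all_day_upright(stride_rows, cow_id="cow") -> EventStream:
    return make_stream([(0.0, DAY_SECONDS, "upright")], stride_rows, cow_id)


# --------------------------------------------------------------------------
# brute-force oracles


def oracle_walking_bouts(strides):
    """Plain scan: runs of strides with end-to-start gaps <= 4 s, >= 3 strides."""
    events = [(float(s), float(s) + float(d) / 1000.0) for s, d, _ in strides]
    bouts, run = [], []
    for ev in events:
        if run and ev[0] - run[-1][1] > 4.0:
            if len(run) >= 3:
                bouts.append((run[0][0], run[-1][1], len(run)))
            run = []
        run.append(ev)
    if len(run) >= 3:
        bouts.append((run[0][0], run[-1][1], len(run)))
    return bouts


def oracle_lying_bouts(posture_rows):
    merged = []
    for s, e, state in posture_rows:
        if state != "lying":
            continue
        if merged and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = [merged[-1][0], e]
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s > 50.0]


def oracle_standing_bouts(posture_rows, walking_bouts):
    merged = []
    for s, e, state in posture_rows:
        if state != "upright":
            continue
        if merged and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = [merged[-1][0], e]
        else:
            merged.append([s, e])
    out = []
    for u0, u1 in merged:
        marks = [(b[0], b[1]) for b in walking_bouts if u0 <= b[0] and b[1] <= u1]
        t, prev_walk = u0, False
        for w0, w1 in marks + [(u1, u1)]:
            dur = w0 - t
            need = 4.0 if prev_walk else 50.0
            if dur > need:
                out.append((t, w0))
            t, prev_walk = w1, True
    return out


def oracle_rank_sum_p(x, y) -> float:
    """Exact two-sided p of the rank-sum test by enumerating assignments."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(x), len(pooled)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n1 * (n + 1) / 2.0
    lo, hi = min(w_obs, 2 * mean_w - w_obs), max(w_obs, 2 * mean_w - w_obs)
    count = 0
    for idx in combinations(range(1, n + 1), n1):
        w = sum(idx)
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            count += 1
    return count / comb(n, n1)


def oracle_auc(scores, labels) -> float:
    """Mean over all (positive, negative) pairs of 1[s+ > s-] + 0.5·1[tie]."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# random small streams for the oracle-equivalence property


def random_small_stream(rng: np.random.Generator) -> EventStream:
    """A valid stream with <= 50 events: random posture blocks + strides."""
    n_blocks = int(rng.integers(1, 8))
    cuts = np.sort(rng.uniform(60.0, DAY_SECONDS - 60.0, size=n_blocks - 1))
    bounds = np.concatenate(([0.0], cuts, [DAY_SECONDS]))
    states = [("lying" if rng.random() < 0.5 else "upright")
              for _ in range(n_blocks)]
    posture = [(bounds[i], bounds[i + 1], states[i]) for i in range(n_blocks)]
    strides = []
    upright = [(s, e) for s, e, st in posture if st == "upright"]
    budget = int(rng.integers(0, 40))
    for _ in range(budget):
        if not upright:
            break
        s, e = upright[int(rng.integers(0, len(upright)))]
        dur = float(rng.uniform(800.0, 2500.0))
        start = float(rng.uniform(s, max(s, e - dur / 1000.0 - 1e-3)))
        if start + dur / 1000.0 < e:
            strides.append((start, dur, float(rng.uniform(80.0, 160.0))))
    strides.sort()
    return make_stream(posture, strides)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
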