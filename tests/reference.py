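"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive, loop-based formulations kept separate from
the package so the production code can be checked against them on random
instances.
"""

from __future__ import annotations

import statistics

import numpy as np


def ref_band(speed, movement=1.0, walk_max=10.0, cycle_max=25.0):
    if speed is None or (isinstance(speed, float) and np.isnan(speed)):
        return 0
    if speed < movement:
        return 0
    if speed < walk_max:
        return 1
    if speed < cycle_max:
        return 2
    return 3


def ref_trips(tidx, speeds, epoch_s=15, movement=1.0, walk_max=10.0, cycle_max=25.0,
              min_trip_min=3.0, max_pause_min=5.0, persistence=4):
    """Enumerate all qualifying trip segments from a speed series.

    ``tidx`` are integer epoch positions on the time grid (not necessarily
    contiguous). Returns (first_pos, last_pos, mode_code) tuples indexing
    into the input arrays.
    """
    bands = [ref_band(s, movement, walk_max, cycle_max) for s in speeds]
    moving = [i for i, b in enumerate(bands) if b > 0]
    gap_ep = int(round(max_pause_min * 60 / epoch_s))
    min_ep = int(np.ceil(min_trip_min * 60 / epoch_s))

    # chain moving epochs into runs: a stationary stretch longer than the
    # allowance breaks the chain
    runs = []
    cur = []
    for pos in moving:
        if cur and tidx[pos] - tidx[cur[-1]] - 1 > gap_ep:
            runs.append(cur)
            cur = []
        cur.append(pos)
    if cur:
        runs.append(cur)

    out = []
    for run in runs:
        # blocks of equal band over the run's moving epochs
        blocks = []
        for pos in run:
            b = bands[pos]
            if blocks and blocks[-1][0] == b:
                blocks[-1][1].append(pos)
            else:
                blocks.append([b, [pos]])
        sustained = [len(members) >= persistence for _, members in blocks]
        if not any(sustained):
            segments = [run]
        else:
            first_sus = sustained.index(True)
            owner_band = []
            last = None
            for k, (b, _) in enumerate(blocks):
                if sustained[k]:
                    last = b
                owner_band.append(last if last is not None else blocks[first_sus][0])
            segments = []
            seg = list(blocks[0][1])
            for k in range(1, len(blocks)):
                if owner_band[k] != owner_band[k - 1]:
                    segments.append(seg)
                    seg = []
                seg.extend(blocks[k][1])
            segments.append(seg)
        for seg in segments:
            extent = tidx[seg[-1]] - tidx[seg[0]] + 1
            if extent < min_ep:
                continue
            med = statistics.median(float(speeds[p]) for p in seg)
            out.append((seg[0], seg[-1], ref_band(med, movement, walk_max, cycle_max)))
    return out


def ref_nonwear_mask(counts, min_epochs=240):
    """Epoch-level non-wear flags by scanning every window: an epoch is
    non-wear iff some all-zero window of length >= min_epochs covers it."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    zero = counts == 0
    mask = np.zeros(n, dtype=bool)
    if n < min_epochs:
        return mask
    window_all_zero = np.convolve(zero.astype(int), np.ones(min_epochs, dtype=int), "valid") == min_epochs
    for start in np.flatnonzero(window_all_zero):
        mask[start:start + min_epochs] = True
    return mask


def random_speed_stream(rng, n):
    """A random epoch stream exercising all bands, pauses and gaps."""
    speeds = np.empty(n)
    i = 0
    while i < n:
        kind = rng.integers(0, 5)
        ln = int(rng.integers(1, 40))
        ln = min(ln, n - i)
        if kind == 0:
            speeds[i:i + ln] = rng.uniform(0, 0.99, ln)
        elif kind == 1:
            speeds[i:i + ln] = rng.uniform(1, 10, ln)
        elif kind == 2:
            speeds[i:i + ln] = rng.uniform(10, 25, ln)
        elif kind == 3:
            speeds[i:i + ln] = rng.uniform(25, 60, ln)
        else:
            speeds[i:i + ln] = np.nan
        i += ln
    return speeds
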