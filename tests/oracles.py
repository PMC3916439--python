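"""Independent brute-force oracles used to cross-check the fast algorithms.

These deliberately re-derive results from first principles (day-by-day
scans, exhaustive candidate searches) and share no code with the package's
implementations.
"""

from __future__ import annotations

import numpy as np


def collapse_oracle(days, collapse_days=30):
    """Episode onsets by a literal day scan of the anchor rule.

    Walk the sorted event days; an event more than ``collapse_days`` after
    the current anchor starts a new episode.
    """
    onsets = []
    anchor = None
    for d in sorted(int(x) for x in days):
        if anchor is None or d - anchor > collapse_days:
            onsets.append(d)
            anchor = d
    return onsets


def exposure_oracle(fills, horizon=800, stockpile=True):
    """Covered-day boolean array from a per-day pill-stock simulation.

    ``fills`` is a list of (day, supply). Under stockpiling, supply
    accumulates in a stock consumed one unit per covered day; without
    stockpiling, a new fill resets remaining stock to its own supply.
    """
    fills = sorted((int(d), int(s)) for d, s in fills)
    covered = np.zeros(horizon, dtype=bool)
    stock = 0
    add = {}
    for d, s in fills:
        add.setdefault(d, []).append(s)
    start = fills[0][0] if fills else horizon
    for day in range(start, horizon):
        if day in add:
            if stockpile:
                stock += sum(add[day])
            else:
                stock = add[day][-1]
        if stock > 0:
            covered[day] = True
            stock -= 1
    return covered


def persistence_oracle(fills, others=(), gap_days=60, horizon=360):
    """(days_persistent, reason) from the covered-day simulation.

    A gap is a maximal uncovered run starting at a runout day; the first gap
    of at least ``gap_days`` (measured to the next fill, or to the horizon)
    is a discontinuation at its start. A different-DMT claim arriving before
    that gap completes switches instead.
    """
    sim_span = horizon + 500
    covered = exposure_oracle(fills, horizon=sim_span)
    disc = None
    if not covered.any():
        if horizon >= gap_days:
            disc = 0
    else:
        day = int(np.argmax(covered))  # first covered day
        while day < sim_span:
            if not covered[day]:
                nxt = day + 1
                while nxt < sim_span and not covered[nxt]:
                    nxt += 1
                gap_len = (nxt - day) if nxt < sim_span else (horizon - day)
                if gap_len >= gap_days:
                    disc = day
                    break
                day = nxt
            else:
                day += 1
        if disc is None and horizon - _runout(covered, sim_span) >= gap_days:
            disc = _runout(covered, sim_span)

    switches = sorted(int(d) for d, _ in others if 0 < int(d) <= horizon)
    for s in switches:
        if disc is None or s < disc + gap_days:
            if s < horizon:
                return s, "switched"
        break
    if disc is not None and disc < horizon:
        return disc, "discontinued"
    return horizon, "censored"


def _runout(covered, span):
    last = int(np.max(np.flatnonzero(covered)))
    return last + 1


def nearest_match_oracle(treated, controls, caliper, order):
    """Greedy matching by exhaustive nearest search (no sorted shortcuts).

    ``treated``/``controls`` are dicts id -> score; ``order`` is the
    processing order of treated ids. Ties break to the lowest control id.
    """
    used = set()
    pairs = []
    for t in order:
        best = None
        for c, sc in controls.items():
            if c in used:
                continue
            dist = abs(sc - treated[t])
            if best is None or dist < best[0] - 1e-15 or (
                abs(dist - best[0]) <= 1e-15 and c < best[1]
            ):
                best = (dist, c)
        if best is not None and best[0] <= caliper + 1e-12:
            used.add(best[1])
            pairs.append((t, best[1], best[0]))
    return pairs


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Two-sample log-rank chi-square by direct tabulation."""
    data = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in data if e})
    obs_a = exp_a = var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in data if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee)
        d_a = sum(1 for tt, ee, g in at_risk if tt == t and ee and g == 0)
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return (obs_a - exp_a) ** 2 / var
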