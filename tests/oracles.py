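"""Independent brute-force reference implementations used only by tests.

These re-derive the expected behaviour of overlap resolution, gap closure
and stop-date reconciliation from first principles (day-by-day simulation,
scalar case analysis), deliberately sharing no code with the package.
"""

from __future__ import annotations

import math


def _round_half_up(v):
    return math.floor(v + 0.5)


# ---------------------------------------------------------------------------
# node 9: which days are exposed, per option, on a day grid
# ---------------------------------------------------------------------------


def exposed_days_stockpile(intervals):
    """Supply-queue simulation: each script adds its duration to a personal
    stockpile consumed one day at a time.  Covers both the 'shift the later
    script' (9a) and 'sum durations from earliest start' (9d) options, whose
    exposed-day sets coincide."""
    if not intervals:
        return set()
    supply_by_day = {}
    for s, e in intervals:
        supply_by_day[int(s)] = supply_by_day.get(int(s), 0) + int(e - s)
    first = min(supply_by_day)
    horizon = first + sum(int(e - s) for s, e in intervals) + max(int(s) for s, _ in intervals)
    days = set()
    supply = 0
    for d in range(first, horizon + 1):
        supply += supply_by_day.get(d, 0)
        if supply > 0:
            days.add(d)
            supply -= 1
    return days


def exposed_days_truncate(intervals):
    """9b: a day is exposed iff the latest-starting script issued on or
    before that day still covers it."""
    days = set()
    if not intervals:
        return days
    srt = sorted(intervals)
    lo = int(min(s for s, _ in srt))
    hi = int(max(e for _, e in srt))
    for d in range(lo, hi):
        covering = [(s, e) for s, e in srt if s <= d]
        if covering and d < covering[-1][1]:
            days.add(d)
    return days


def exposed_days_union(intervals):
    """9c: plain union of the script intervals."""
    days = set()
    for s, e in intervals:
        days.update(range(int(s), int(e)))
    return days


def exposed_days_drop_later(intervals):
    """9e: keep each script only if it starts at or after the end of the
    last kept script."""
    days = set()
    running = -math.inf
    for s, e in sorted(intervals):
        if s >= running:
            days.update(range(int(s), int(e)))
            running = e
    return days


EXPOSED_DAY_ORACLES = {
    "9a": exposed_days_stockpile,
    "9b": exposed_days_truncate,
    "9c": exposed_days_union,
    "9d": exposed_days_stockpile,
    "9e": exposed_days_drop_later,
}


# ---------------------------------------------------------------------------
# node 10: gap bridging on disjoint sorted intervals
# ---------------------------------------------------------------------------


def bridged_days(intervals, x):
    """10b(x): exposed days plus any gap of fewer than x days between
    consecutive episodes."""
    days = exposed_days_union(intervals)
    srt = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
        if s2 - e1 < x:
            days.update(range(int(e1), int(s2)))
    return days


def continuous_days(intervals):
    """10c: everything from the first start to the last stop."""
    if not intervals:
        return set()
    return set(range(int(min(s for s, _ in intervals)), int(max(e for _, e in intervals))))


# ---------------------------------------------------------------------------
# node 6d: scalar stop-date reconciliation
# ---------------------------------------------------------------------------


def reconcile_6d(numdays, dose_duration, qty_ndd, x):
    """Case analysis of the reconciliation rule.  Candidates may be None.

    One candidate: use it.  Two equal: that date; two within x days: their
    mean (rounded half-up); else missing.  Three all equal: that date;
    otherwise the mean of the closest pair if within x days, preferring the
    pair involving qty/ndd (then numdays) when distances tie.
    """
    present = [v for v in (numdays, dose_duration, qty_ndd) if v is not None]
    if len(present) == 0:
        return None
    if len(present) == 1:
        return present[0]
    if len(present) == 2:
        v1, v2 = present
        if v1 == v2:
            return v1
        if abs(v1 - v2) <= x:
            return _round_half_up((v1 + v2) / 2)
        return None
    a, b, c = numdays, dose_duration, qty_ndd
    if a == b == c:
        return a
    pairs = [
        (abs(a - c), 0, (a + c) / 2),  # involves qty_ndd and numdays
        (abs(b - c), 1, (b + c) / 2),  # involves qty_ndd
        (abs(a - b), 2, (a + b) / 2),
    ]
    dist, _, mean = min(pairs)
    if dist <= x:
        return _round_half_up(mean)
    return None
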