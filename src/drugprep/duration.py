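"""Step B: derive a stop date per prescription (nodes 6 and 7).

Primary-care prescription records carry no stop date; it must be computed
from one of three duration sources: the prescriber-entered treatment days
(``numdays``), the database-derived duration (``dose_duration``), or the
implied supply ``qty / ndd``.  Node 6 selects the source (or reconciles
several); node 7 handles records whose stop date is still missing — any
record left without a stop date after node 7 is dropped.

Derived durations are rounded half-up to whole days; a derived duration of
less than one day yields no candidate (a zero-length prescription carries no
usable exposure time).  The mean of two dates with an odd day difference
rounds half-up to the later day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AuditLedger, parse_token, round_half_up

__all__ = [
    "candidate_stop_dates",
    "select_stop_date",
    "assign_stop_dates",
    "resolve_missing_stop",
]

_CAND_COLS = ["from_numdays", "from_dose_duration", "from_qty_ndd"]


def candidate_stop_dates(records: pd.DataFrame) -> pd.DataFrame:
    """Stop-date candidates from each duration source, one row per record.

    ``from_numdays`` = start + numdays; ``from_dose_duration`` = start +
    dose_duration; ``from_qty_ndd`` = start + round(qty / ndd).  A candidate
    is missing when its source is missing, non-positive, or rounds to less
    than one day.
    """
    start = records["start"].to_numpy(float)

    def _from_duration(dur):
        dur = round_half_up(np.asarray(dur, dtype=float))
        dur = np.where(dur >= 1, dur, np.nan)
        return start + dur

    qty = records["qty"].to_numpy(float)
    ndd = records["ndd"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        supply = np.where((ndd > 0) & ~np.isnan(qty), qty / ndd, np.nan)

    return pd.DataFrame(
        {
            "from_numdays": _from_duration(records["numdays"]),
            "from_dose_duration": _from_duration(records["dose_duration"]),
            "from_qty_ndd": _from_duration(supply),
        },
        index=records.index,
    )


def select_stop_date(candidates: pd.DataFrame, node6_option: str) -> pd.Series:
    """Apply the node-6 option to candidate stop dates (vectorised).

    6a/6b/6c take a single source and are missing when it is.  6d(x)
    reconciles whatever candidates exist:

    * one candidate: use it;
    * two, equal: that date; two, unequal but within x days: their mean;
      two, further apart than x: missing;
    * three, all equal: that date; three, not all equal: the mean of the
      closest pair if that pair is within x days, else missing.

    "Within x days" is inclusive; date means are rounded half-up.  When two
    pairs are equally close, the pair involving ``from_qty_ndd`` wins (the
    best-populated source), and between the two such pairs the one involving
    ``from_numdays`` wins.
    """
    opt = parse_token(node6_option)
    if opt.node_id != 6:
        raise ValueError(f"option {node6_option!r} does not belong to node 6")

    a = candidates["from_numdays"].to_numpy(float)
    b = candidates["from_dose_duration"].to_numpy(float)
    c = candidates["from_qty_ndd"].to_numpy(float)

    if opt.letter == "a":
        out = a.copy()
    elif opt.letter == "b":
        out = b.copy()
    elif opt.letter == "c":
        out = c.copy()
    elif opt.letter == "d":
        if opt.param is None:
            raise ValueError("6d requires a day tolerance, e.g. '6d(30)'")
        out = _reconcile_6d(a, b, c, float(opt.param))
    else:
        raise ValueError(f"unknown node-6 option {node6_option!r}")
    return pd.Series(out, index=candidates.index, name="stop")


def _reconcile_6d(a, b, c, x):
    pa, pb, pc = ~np.isnan(a), ~np.isnan(b), ~np.isnan(c)
    n = pa.astype(int) + pb + pc
    out = np.full(a.shape, np.nan)

    # single candidate
    for v, p in ((a, pa), (b, pb), (c, pc)):
        m = (n == 1) & p
        out[m] = v[m]

    # two candidates
    for v1, v2, p1, p2 in ((a, b, pa, pb), (a, c, pa, pc), (b, c, pb, pc)):
        m = (n == 2) & p1 & p2
        if not m.any():
            continue
        diff = np.abs(v1 - v2)
        use = m & (diff <= x)
        out[use] = round_half_up((v1[use] + v2[use]) / 2.0)

    # three candidates: mean of the closest pair if within x days.
    m3 = n == 3
    if m3.any():
        d_ab = np.abs(a - b)
        d_ac = np.abs(a - c)
        d_bc = np.abs(b - c)
        # tie preference: pairs involving from_qty_ndd first, then from_numdays
        pref = np.argmin(
            np.stack([d_ac, d_bc, d_ab + 0.0]), axis=0
        )  # argmin takes the first minimum -> preference order ac, bc, ab
        dmin = np.minimum(np.minimum(d_ac, d_bc), d_ab)
        mean_by_pref = np.stack(
            [
                round_half_up((a + c) / 2.0),
                round_half_up((b + c) / 2.0),
                round_half_up((a + b) / 2.0),
            ]
        )
        chosen = np.take_along_axis(mean_by_pref, pref[None, :], axis=0)[0]
        use = m3 & (dmin <= x)
        out[use] = chosen[use]
    return out


def assign_stop_dates(
    records: pd.DataFrame,
    node6_option: str,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Node 6: attach a ``stop`` column; missing where unresolvable."""
    df = records.copy()
    stops = select_stop_date(candidate_stop_dates(df), node6_option)
    df["stop"] = stops
    if ledger is not None:
        resolved = int(stops.notna().sum())
        ledger.record(
            "node6", len(df), modified=resolved, set_missing=len(df) - resolved
        )
    return df


def resolve_missing_stop(
    records: pd.DataFrame,
    node7_option: str,
    plausibility: pd.DataFrame,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Node 7: impute or drop records whose stop date is still missing.

    Options: 7a keep missing (the record is then dropped); 7b patient mean
    observed duration for that product; 7c population mean duration for that
    product (falling back to the product default); 7d the product's default
    duration; 7e carry forward the duration of the patient's previous
    resolved prescription for that product.  Any record still missing a stop
    date afterwards is dropped and counted in the ledger.

    Donor durations are observed ``stop - start`` values as resolved by node
    6, frozen before imputation.
    """
    opt = parse_token(node7_option)
    if opt.node_id != 7:
        raise ValueError(f"option {node7_option!r} does not belong to node 7")
    df = records.copy()
    missing = df["stop"].isna().to_numpy()
    n_in = len(df)
    imputed = 0

    if opt.letter != "a" and missing.any():
        dur = (df["stop"] - df["start"]).astype(float)  # NaN where unresolved
        pid, prod = df["patient_id"], df["product_code"]
        ref = plausibility.set_index("product_code")
        default = prod.map(
            ref["default_duration_days"] if "default_duration_days" in ref else pd.Series(dtype=float)
        ).to_numpy(float)

        pop = prod.map(dur.groupby(prod).mean()).to_numpy(float)
        pop = np.where(np.isnan(pop), default, pop)

        if opt.letter == "b":
            idx = pd.MultiIndex.from_arrays([pid, prod])
            fill = dur.groupby([pid, prod]).mean().reindex(idx).to_numpy(float)
        elif opt.letter == "c":
            fill = pop
        elif opt.letter == "d":
            fill = default
        elif opt.letter == "e":
            order = df.sort_values(["patient_id", "product_code", "start"], kind="mergesort")
            keys = [order["patient_id"], order["product_code"]]
            prev = dur.reindex(order.index).groupby(keys).shift(1)
            prev = prev.groupby(keys).ffill()
            fill = prev.reindex(df.index).to_numpy(float)
        else:
            raise ValueError(f"unknown node-7 option {node7_option!r}")

        fill = round_half_up(fill)
        fill = np.where(fill >= 1, fill, np.nan)
        new_stop = df["stop"].to_numpy(float)
        new_stop[missing] = (df["start"].to_numpy(float) + fill)[missing]
        imputed = int(missing.sum() - np.isnan(new_stop).sum())
        df["stop"] = new_stop

    still_missing = df["stop"].isna()
    dropped = int(still_missing.sum())
    df = df.loc[~still_missing].copy()
    if ledger is not None:
        ledger.record("node7", n_in, modified=imputed, dropped=dropped)
    return df
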