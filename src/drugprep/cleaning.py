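"""Step A: field cleaning of raw prescription records (decision nodes 1-5).

Nodes 1/3/5 handle *implausible* values of ``qty`` / ``ndd`` / the two
duration fields (values outside the per-product clinical plausibility bounds);
nodes 2/4 handle *missing* ``qty`` / ``ndd``.  No node in Step A drops
records.

Imputation statistics (population and patient means, carry-forward values)
are computed once from the snapshot of the data as it enters each node, on
plausible (in-bounds) non-missing values only, so results do not depend on
row order within a node and re-running a node is a no-op.  Bounds are inclusive.  Fallback chain when donors
are unavailable: patient mean -> product population mean -> product default;
carry-forward with no prior prescription leaves the value missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AuditLedger, parse_token, round_half_up, logger

__all__ = ["clean_quantity", "clean_daily_dose", "clean_duration_fields"]

# field -> (lower bound col, upper bound col, default col)
_FIELD_SPEC = {
    "qty": ("qty_min", "qty_max", "default_qty"),
    "ndd": ("ndd_min", "ndd_max", "default_ndd"),
    "numdays": ("dur_min", "dur_max", "default_duration_days"),
    "dose_duration": ("dur_min", "dur_max", "default_duration_days"),
}


def _check_option(token: str, node_id: int) -> str:
    opt = parse_token(token)
    if opt.node_id != node_id:
        raise ValueError(f"option {token!r} does not belong to node {node_id}")
    return opt.letter


def _aligned_bounds(df: pd.DataFrame, plausibility: pd.DataFrame, fld: str):
    """Per-row (lo, hi, default) arrays for *fld*, aligned to *df*.

    Unknown product codes get (-inf, +inf, NaN): every value is treated as
    plausible and defaults are unavailable (logged once per call).
    """
    lo_c, hi_c, def_c = _FIELD_SPEC[fld]
    ref = plausibility.set_index("product_code")
    codes = df["product_code"]
    known = codes.isin(ref.index)
    if not known.all():
        unknown = sorted(set(codes[~known]))
        logger.warning(
            "no plausibility entry for %d product code(s) (e.g. %s); "
            "treating their values as plausible",
            len(unknown),
            unknown[:5],
        )
    lo = codes.map(ref[lo_c]).to_numpy(float)
    hi = codes.map(ref[hi_c]).to_numpy(float)
    default = codes.map(ref[def_c]).to_numpy(float)
    lo = np.where(np.isnan(lo), -np.inf, lo)
    hi = np.where(np.isnan(hi), np.inf, hi)
    return lo, hi, default


class _FieldStats:
    """Donor statistics for one field, frozen from the entering snapshot."""

    def __init__(self, df: pd.DataFrame, fld: str, lo, hi, default):
        vals = df[fld].astype(float)
        plaus = vals.notna() & (vals.to_numpy(float) >= lo) & (vals.to_numpy(float) <= hi)
        donor = vals.where(plaus)  # plausible values only, NaN elsewhere

        prod = df["product_code"]
        pid = df["patient_id"]

        pop = donor.groupby(prod).mean()
        # population fallback: product default where no plausible donor exists
        self.pop_mean_by_row = prod.map(pop).to_numpy(float)
        self.pop_mean_by_row = np.where(
            np.isnan(self.pop_mean_by_row), default, self.pop_mean_by_row
        )

        pat = donor.groupby([pid, prod]).mean()
        idx = pd.MultiIndex.from_arrays([pid, prod])
        pat_by_row = pat.reindex(idx).to_numpy(float)
        # patient mean falls back to population mean, then default
        self.patient_mean_by_row = np.where(
            np.isnan(pat_by_row), self.pop_mean_by_row, pat_by_row
        )

        # carry forward: most recent plausible value from a strictly earlier
        # prescription of the same patient/product (ties broken by row order)
        order = df.sort_values(["patient_id", "product_code", "start"], kind="mergesort")
        keys = [order["patient_id"], order["product_code"]]
        prev = donor.reindex(order.index).groupby(keys).shift(1)
        prev = prev.groupby(keys).ffill()
        self.carry_forward_by_row = prev.reindex(df.index).to_numpy(float)

        self.default_by_row = default


def _apply_field_node(
    df: pd.DataFrame,
    fld: str,
    mode: str,  # "implausible" or "missing"
    letter_actions: dict[str, str],
    letter: str,
    stats: _FieldStats,
    lo,
    hi,
    integer: bool = False,
):
    """Apply one node's option to one field; returns (modified, set_missing)."""
    vals = df[fld].to_numpy(float)
    if mode == "implausible":
        mask = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
    else:
        mask = np.isnan(vals)
    action = letter_actions[letter]
    if action == "leave" or not mask.any():
        return 0, 0

    new = vals.copy()
    if action == "set_missing":
        new[mask] = np.nan
        df[fld] = new
        return 0, int(mask.sum())

    if action == "pop_mean":
        fill = stats.pop_mean_by_row
    elif action == "patient_mean":
        fill = stats.patient_mean_by_row
    elif action == "carry_forward":
        fill = stats.carry_forward_by_row
    elif action == "default":
        fill = stats.default_by_row
    elif action == "cap":
        fill = np.clip(vals, lo, hi)
    else:  # pragma: no cover - registry and actions are fixed together
        raise ValueError(f"unknown action {action!r}")

    fill = np.asarray(fill, dtype=float)
    if integer:
        fill = round_half_up(fill)
    new[mask] = fill[mask]
    changed = mask & ~_same(vals, new)
    became_missing = mask & np.isnan(new) & ~np.isnan(vals)
    df[fld] = new
    return int((changed & ~became_missing).sum()), int(became_missing.sum())


def _same(a, b):
    return (a == b) | (np.isnan(a) & np.isnan(b))


def clean_quantity(
    records: pd.DataFrame,
    node1_option: str,
    node2_option: str,
    plausibility: pd.DataFrame,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Nodes 1 and 2: implausible then missing total quantity (``qty``).

    Node 1 options: 1a leave as-is; 1b set missing; 1c product-population
    mean of plausible values; 1d patient mean; 1e cap at the nearest bound.
    Node 2 options: 2a leave missing; 2b population mean; 2c patient mean;
    2d carry forward the patient's previous value for that product; 2e the
    product default quantity.
    """
    l1 = _check_option(node1_option, 1)
    l2 = _check_option(node2_option, 2)
    df = records.copy()
    lo, hi, default = _aligned_bounds(df, plausibility, "qty")

    # donor statistics are frozen at entry to each node (node 2 sees the
    # post-node-1 state), keeping each node order-independent and the whole
    # operation idempotent
    node1_actions = {"a": "leave", "b": "set_missing", "c": "pop_mean",
                     "d": "patient_mean", "e": "cap"}
    stats = _FieldStats(df, "qty", lo, hi, default)
    mod, miss = _apply_field_node(df, "qty", "implausible", node1_actions, l1, stats, lo, hi)
    if ledger is not None:
        ledger.record("node1", len(df), modified=mod, set_missing=miss)

    node2_actions = {"a": "leave", "b": "pop_mean", "c": "patient_mean",
                     "d": "carry_forward", "e": "default"}
    stats = _FieldStats(df, "qty", lo, hi, default)
    mod, miss = _apply_field_node(df, "qty", "missing", node2_actions, l2, stats, lo, hi)
    if ledger is not None:
        ledger.record("node2", len(df), modified=mod, set_missing=miss)
    return df


def clean_daily_dose(
    records: pd.DataFrame,
    node3_option: str,
    node4_option: str,
    plausibility: pd.DataFrame,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Nodes 3 and 4: implausible then missing numeric daily dose (``ndd``).

    Node 3 mirrors node 1 (3a-3e).  Node 4 options: 4a leave missing; 4b
    patient mean; 4c product-population mean; 4d carry forward; 4e product
    default daily dose.  Note the patient/population letter order differs
    between nodes 2 and 4.
    """
    l3 = _check_option(node3_option, 3)
    l4 = _check_option(node4_option, 4)
    df = records.copy()
    lo, hi, default = _aligned_bounds(df, plausibility, "ndd")

    node3_actions = {"a": "leave", "b": "set_missing", "c": "pop_mean",
                     "d": "patient_mean", "e": "cap"}
    stats = _FieldStats(df, "ndd", lo, hi, default)
    mod, miss = _apply_field_node(df, "ndd", "implausible", node3_actions, l3, stats, lo, hi)
    if ledger is not None:
        ledger.record("node3", len(df), modified=mod, set_missing=miss)

    node4_actions = {"a": "leave", "b": "patient_mean", "c": "pop_mean",
                     "d": "carry_forward", "e": "default"}
    stats = _FieldStats(df, "ndd", lo, hi, default)
    mod, miss = _apply_field_node(df, "ndd", "missing", node4_actions, l4, stats, lo, hi)
    if ledger is not None:
        ledger.record("node4", len(df), modified=mod, set_missing=miss)
    return df


def clean_duration_fields(
    records: pd.DataFrame,
    node5_option: str,
    plausibility: pd.DataFrame,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Node 5: implausible duration fields, applied independently to both
    ``numdays`` and ``dose_duration``.

    Options: 5a leave; 5b set missing; 5c cap at the nearest bound; 5d
    population mean plausible duration; 5e patient mean plausible duration.
    Imputed durations are rounded half-up to whole days.
    """
    l5 = _check_option(node5_option, 5)
    df = records.copy()
    node5_actions = {"a": "leave", "b": "set_missing", "c": "cap",
                     "d": "pop_mean", "e": "patient_mean"}
    tot_mod = tot_miss = 0
    for fld in ("numdays", "dose_duration"):
        lo, hi, default = _aligned_bounds(df, plausibility, fld)
        stats = _FieldStats(df, fld, lo, hi, default)
        mod, miss = _apply_field_node(
            df, fld, "implausible", node5_actions, l5, stats, lo, hi, integer=True
        )
        tot_mod += mod
        tot_miss += miss
    if ledger is not None:
        ledger.record("node5", len(df), modified=tot_mod, set_missing=tot_miss)
    return df
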