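"""Step C: from dated prescriptions to disjoint exposure episodes (nodes 8-10).

Node 8 collapses multiple same-product prescriptions issued on the same day;
records are then pooled into drug-class episodes.  Node 9 reconciles
overlapping successive episodes of one class; node 10 optionally bridges
short gaps between successive episodes.  Finally the timeline is clipped to
each patient's follow-up window.

Overlap and gap resolution operate within drug class (all products of a
class pooled), in start-date order with a single left-to-right sweep and a
running exposure end.  "Gap < x days" is a strict inequality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AuditLedger, parse_token, round_half_up, logger

__all__ = [
    "collapse_same_day",
    "to_class_episodes",
    "resolve_overlaps",
    "close_gaps",
    "build_exposure_timeline",
    "clip_to_followup",
]

EPISODE_COLUMNS = ["patient_id", "drug_class", "start", "stop"]


def collapse_same_day(
    records: pd.DataFrame,
    node8_option: str,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Node 8: collapse same-patient, same-product, same-start-date groups.

    8a keep the longest duration; 8b the shortest; 8c one record of summed
    duration; 8d one record of mean duration (rounded half-up); 8e keep all
    records and let node 9 sort them out.
    """
    opt = parse_token(node8_option)
    if opt.node_id != 8:
        raise ValueError(f"option {node8_option!r} does not belong to node 8")
    n_in = len(records)
    if opt.letter == "e" or n_in == 0:
        if ledger is not None:
            ledger.record("node8", n_in)
        return records.copy()

    df = records.copy()
    dur = df["stop"].astype(float) - df["start"].astype(float)
    keys = ["patient_id", "product_code", "start"]
    agg = {"a": "max", "b": "min", "c": "sum", "d": "mean"}[opt.letter]
    gdur = dur.groupby([df[k] for k in keys]).agg(agg)
    if opt.letter == "d":
        gdur = gdur.map(round_half_up)
    out = gdur.reset_index()
    out.columns = keys + ["_dur"]
    out["stop"] = out["start"] + out["_dur"]
    out = out.drop(columns="_dur")
    if ledger is not None:
        ledger.record("node8", n_in, merged=n_in - len(out))
    return out


def to_class_episodes(records: pd.DataFrame, plausibility: pd.DataFrame) -> pd.DataFrame:
    """Pool product-level records into drug-class episodes.

    Unknown product codes keep their own code as the class label (logged).
    """
    ref = plausibility.set_index("product_code")["drug_class"]
    cls = records["product_code"].map(ref)
    if cls.isna().any():
        logger.warning(
            "%d record(s) with product codes absent from the plausibility "
            "table; using the product code itself as drug class",
            int(cls.isna().sum()),
        )
        cls = cls.fillna(records["product_code"].astype(str))
    out = pd.DataFrame(
        {
            "patient_id": records["patient_id"],
            "drug_class": cls,
            "start": records["start"].astype(float),
            "stop": records["stop"].astype(float),
        }
    )
    return out.sort_values(
        ["patient_id", "drug_class", "start", "stop"], kind="mergesort"
    ).reset_index(drop=True)


def _grouped_arrays(episodes: pd.DataFrame):
    df = episodes.sort_values(
        ["patient_id", "drug_class", "start", "stop"], kind="mergesort"
    ).reset_index(drop=True)
    grp = (
        df[["patient_id", "drug_class"]]
        .ne(df[["patient_id", "drug_class"]].shift())
        .any(axis=1)
        .cumsum()
        .to_numpy()
    )
    return df, grp


def resolve_overlaps(
    episodes: pd.DataFrame,
    node9_option: str,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Node 9: reconcile overlapping successive episodes of one class.

    9a stockpiling: a later overlapping episode is delayed to the running
    exposure end, its duration preserved; 9b the earlier episode is truncated
    at the later's start; 9c overlapping episodes are merged to their union
    (surplus supply discarded); 9d overlapping runs are merged into one
    episode whose duration is the sum of the constituent durations, from the
    earliest start; 9e a later overlapping episode is dropped.  Output is
    overlap-free.
    """
    opt = parse_token(node9_option)
    if opt.node_id != 9:
        raise ValueError(f"option {node9_option!r} does not belong to node 9")
    n_in = len(episodes)
    df, grp = _grouped_arrays(episodes)
    starts = df["start"].to_numpy(float)
    stops = df["stop"].to_numpy(float)
    pid = df["patient_id"].to_numpy()
    cls = df["drug_class"].to_numpy()

    out_pid, out_cls, out_start, out_stop = [], [], [], []
    modified = merged = dropped = 0

    i = 0
    n = len(df)
    letter = opt.letter
    while i < n:
        g = grp[i]
        # current output episode for this group
        cur_s, cur_e = starts[i], stops[i]
        j = i + 1
        while j < n and grp[j] == g:
            s, e = starts[j], stops[j]
            if s >= cur_e:  # no overlap: flush current, start fresh
                out_pid.append(pid[i]); out_cls.append(cls[i])
                out_start.append(cur_s); out_stop.append(cur_e)
                cur_s, cur_e = s, e
            elif letter == "a":  # stockpile: delay, keep duration
                dur = e - s
                out_pid.append(pid[i]); out_cls.append(cls[i])
                out_start.append(cur_s); out_stop.append(cur_e)
                cur_s, cur_e = cur_e, cur_e + dur
                modified += 1
            elif letter == "b":  # truncate the earlier at the later's start
                if s > cur_s:
                    out_pid.append(pid[i]); out_cls.append(cls[i])
                    out_start.append(cur_s); out_stop.append(s)
                    modified += 1
                else:  # identical start: earlier vanishes entirely
                    merged += 1
                cur_s, cur_e = s, e
            elif letter == "c":  # union
                cur_e = max(cur_e, e)
                merged += 1
            elif letter == "d":  # sum durations from the earliest start
                cur_e = cur_e + (e - s)
                merged += 1
            elif letter == "e":  # drop the later overlapping record
                dropped += 1
            else:  # pragma: no cover
                raise ValueError(f"unknown node-9 option {node9_option!r}")
            j += 1
        out_pid.append(pid[i]); out_cls.append(cls[i])
        out_start.append(cur_s); out_stop.append(cur_e)
        i = j

    out = pd.DataFrame(
        {
            "patient_id": out_pid,
            "drug_class": out_cls,
            "start": out_start,
            "stop": out_stop,
        }
    )
    out = out.sort_values(
        ["patient_id", "drug_class", "start", "stop"], kind="mergesort"
    ).reset_index(drop=True)
    if ledger is not None:
        ledger.record("node9", n_in, modified=modified, merged=merged, dropped=dropped)
    return out


def close_gaps(
    episodes: pd.DataFrame,
    node10_option: str,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Node 10: bridge short gaps between successive episodes of one class.

    10a never bridge; 10b(x) merge consecutive episodes whose gap is
    strictly less than x days, applied left-to-right until stable; 10c treat
    the patient as continuously exposed from first start to last stop.
    """
    opt = parse_token(node10_option)
    if opt.node_id != 10:
        raise ValueError(f"option {node10_option!r} does not belong to node 10")
    n_in = len(episodes)
    if opt.letter == "a" or n_in == 0:
        if ledger is not None:
            ledger.record("node10", n_in)
        return episodes.sort_values(
            ["patient_id", "drug_class", "start", "stop"], kind="mergesort"
        ).reset_index(drop=True)

    df, grp = _grouped_arrays(episodes)
    starts = df["start"].to_numpy(float)
    stops = df["stop"].to_numpy(float)

    if opt.letter == "c":
        out = (
            df.groupby(["patient_id", "drug_class"], sort=False)
            .agg(start=("start", "min"), stop=("stop", "max"))
            .reset_index()
        )
    elif opt.letter == "b":
        x = float(opt.param)
        keep_s, keep_e, keep_idx = [], [], []
        i, n = 0, len(df)
        while i < n:
            g = grp[i]
            cur_s, cur_e = starts[i], stops[i]
            j = i + 1
            while j < n and grp[j] == g:
                if starts[j] - cur_e < x:  # strict: gap < x bridges
                    cur_e = max(cur_e, stops[j])
                else:
                    keep_idx.append(i); keep_s.append(cur_s); keep_e.append(cur_e)
                    cur_s, cur_e = starts[j], stops[j]
                j += 1
            keep_idx.append(i); keep_s.append(cur_s); keep_e.append(cur_e)
            i = j
        out = pd.DataFrame(
            {
                "patient_id": df["patient_id"].to_numpy()[keep_idx],
                "drug_class": df["drug_class"].to_numpy()[keep_idx],
                "start": keep_s,
                "stop": keep_e,
            }
        )
    else:
        raise ValueError(f"unknown node-10 option {node10_option!r}")

    out = out.sort_values(
        ["patient_id", "drug_class", "start", "stop"], kind="mergesort"
    ).reset_index(drop=True)
    if ledger is not None:
        ledger.record("node10", n_in, merged=n_in - len(out))
    return out


def build_exposure_timeline(
    episodes: pd.DataFrame, entry: float, exit: float
) -> pd.DataFrame:
    """Clip one patient's episodes to the follow-up window [entry, exit).

    Episodes entirely outside follow-up are removed; the output is disjoint
    and sorted, and its complement within follow-up is the unexposed
    person-time.
    """
    if not exit > entry:
        raise ValueError("follow-up exit must be after entry")
    df = episodes.copy()
    df["start"] = df["start"].clip(lower=entry)
    df["stop"] = df["stop"].clip(upper=exit)
    df = df.loc[df["stop"] > df["start"]]
    return df.sort_values(["drug_class", "start"], kind="mergesort").reset_index(
        drop=True
    )


def clip_to_followup(
    episodes: pd.DataFrame,
    followup: pd.DataFrame,
    ledger: AuditLedger | None = None,
) -> pd.DataFrame:
    """Clip all patients' episodes to their follow-up windows.

    *followup* has one row per patient with ``entry`` and ``exit`` columns.
    Patients absent from the follow-up table contribute no episodes.
    """
    n_in = len(episodes)
    fu = followup.set_index("patient_id")
    entry = episodes["patient_id"].map(fu["entry"]).to_numpy(float)
    exit_ = episodes["patient_id"].map(fu["exit"]).to_numpy(float)
    df = episodes.copy()
    df["start"] = np.maximum(df["start"].to_numpy(float), entry)
    df["stop"] = np.minimum(df["stop"].to_numpy(float), exit_)
    clipped = (df["start"].to_numpy() != episodes["start"].to_numpy(float)) | (
        df["stop"].to_numpy() != episodes["stop"].to_numpy(float)
    )
    keep = (df["stop"] > df["start"]).to_numpy() & ~np.isnan(
        df["start"].to_numpy(float)
    )
    out = (
        df.loc[keep]
        .sort_values(["patient_id", "drug_class", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    if ledger is not None:
        ledger.record(
            "clip",
            n_in,
            modified=int((clipped & keep).sum()),
            dropped=n_in - len(out),
        )
    return out
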