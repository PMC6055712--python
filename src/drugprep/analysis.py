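"""Downstream analysis: time-varying exposure vs outcome hazard.

Each patient's follow-up is partitioned into counting-process rows
alternating between exposed and unexposed person-time; a Cox proportional
hazards model (no covariates) contrasts exposure states, and a two-stage
sensitivity experiment quantifies how preparation assumptions move the
estimate: stage 1 runs a set of random pathways, stage 2 the primary pathway
plus all of its one-at-a-time variants.

Conventions: exposure is a left-continuous (predictable) process, so the
state at an event on day *d* is the state just before *d*; ties between
event days are handled with the Breslow approximation (day-granular data
guarantee ties); confidence intervals are Wald on the log scale with 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import AuditLedger, DecisionRegistry, PathwaySpec, logger
from .pathways import one_at_a_time_variants, run_pathway, sample_random_pathways

__all__ = [
    "PathwayResult",
    "split_person_time",
    "build_person_time",
    "fit_exposure_model",
    "sensitivity_experiment",
    "summarize_results",
    "plot_results",
]

PERSON_TIME_COLUMNS = ["patient_id", "start", "stop", "exposed", "event"]

# fits whose log-HR magnitude or SE exceed these are flagged non-estimable
# (monotone partial likelihood drifting to an infinite estimate)
_MAX_ABS_LOG_HR = 15.0
_MAX_SE = 50.0


@dataclass
class PathwayResult:
    """Effect estimate and audit counts for one executed pathway."""

    pathway: str
    log_hr: float
    se: float
    n_records_dropped: int
    estimable: bool
    stage: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_hr - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_hr + 1.96 * self.se))


def split_person_time(
    timeline: pd.DataFrame,
    entry: float,
    exit: float,
    event_day: float | None = None,
) -> pd.DataFrame:
    """Partition one patient's follow-up into exposure-state rows.

    *timeline* holds the patient's clipped exposure episodes (disjoint,
    sorted).  Rows are half-open ``[start, stop)`` and alternate between
    exposed and unexposed; follow-up is censored at the event.  The event is
    assigned to the final row, whose exposure state is the state just before
    the event day (exposure is a predictable process).  An event outside
    ``(entry, exit]`` is ignored with a warning.
    """
    if not exit > entry:
        raise ValueError("exit must be after entry")
    end = exit
    has_event = event_day is not None and not np.isnan(event_day)
    if has_event:
        if not entry < event_day <= exit:
            logger.warning(
                "event day %s outside follow-up (%s, %s]; ignored",
                event_day, entry, exit,
            )
            has_event = False
        else:
            end = float(event_day)

    eps = [
        (max(float(s), entry), min(float(e), end))
        for s, e in zip(timeline["start"], timeline["stop"])
    ]
    eps = [(s, e) for s, e in eps if e > s]

    cuts = sorted({entry, end, *(b for se in eps for b in se if entry < b < end)})
    rows = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        exposed = any(a <= s < b for a, b in eps)
        rows.append((s, e, int(exposed), 0))
    if has_event and rows:
        s, e, exposed, _ = rows[-1]
        rows[-1] = (s, e, exposed, 1)
    return pd.DataFrame(rows, columns=["start", "stop", "exposed", "event"])


def build_person_time(
    timeline: pd.DataFrame, followup: pd.DataFrame
) -> pd.DataFrame:
    """Person-time rows for every patient in the follow-up table."""
    by_patient = dict(tuple(timeline.groupby("patient_id"))) if len(timeline) else {}
    empty = timeline.iloc[0:0]
    out = []
    for row in followup.itertuples(index=False):
        eps = by_patient.get(row.patient_id, empty)
        rows = split_person_time(eps, row.entry, row.exit, row.event_day)
        rows.insert(0, "patient_id", row.patient_id)
        out.append(rows)
    if not out:
        return pd.DataFrame(columns=PERSON_TIME_COLUMNS)
    return pd.concat(out, ignore_index=True)


def fit_exposure_model(rows: pd.DataFrame, referent=0) -> dict:
    """Cox partial-likelihood fit of exposure state vs outcome hazard.

    *rows* are counting-process person-time rows; ``exposed`` may be binary
    or a class label, contrasted against *referent*.  Returns a dict with
    ``log_hr``, ``se`` (for the first non-referent level; all levels under
    ``levels``) and ``estimable``.  Non-estimable fits (no events, a level
    with zero events or zero person-time, monotone likelihood, failed
    convergence) are reported with ``estimable=False``, never raised.
    """
    out = {"log_hr": np.nan, "se": np.nan, "estimable": False, "levels": {}}
    if len(rows) == 0 or rows["event"].sum() < 1:
        return out
    levels = sorted(set(rows["exposed"]) - {referent}, key=str)
    if not levels:
        return out
    persontime = (rows["stop"] - rows["start"]).groupby(rows["exposed"]).sum()
    events = rows["event"].groupby(rows["exposed"]).sum()
    for lev in [referent, *levels]:
        if persontime.get(lev, 0) <= 0 or events.get(lev, 0) < 1:
            return out

    X = np.column_stack([(rows["exposed"] == lev).astype(float) for lev in levels])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.PHReg(
                rows["stop"].to_numpy(float),
                X,
                status=rows["event"].to_numpy(int),
                entry=rows["start"].to_numpy(float),
                ties="breslow",
            )
            res = model.fit()
    except Exception:  # singular information, failed convergence, ...
        return out
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    ok = (
        np.all(np.isfinite(params))
        and np.all(np.isfinite(bse))
        and np.all(np.abs(params) < _MAX_ABS_LOG_HR)
        and np.all(bse < _MAX_SE)
        and np.all(bse > 0)
    )
    if not ok:
        return out
    out["levels"] = {lev: (float(p), float(s)) for lev, p, s in zip(levels, params, bse)}
    out["log_hr"] = float(params[0])
    out["se"] = float(bse[0])
    out["estimable"] = True
    return out


def _execute_and_fit(
    raw, spec, plausibility, followup, stage: str
) -> tuple[PathwayResult, AuditLedger]:
    try:
        timeline, ledger = run_pathway(raw, spec, plausibility, followup)
        rows = build_person_time(timeline, followup)
        fit = fit_exposure_model(rows)
    except Exception:  # a pathway failure must never abort the experiment
        logger.exception("pathway %s failed", spec.serialize())
        return (
            PathwayResult(spec.serialize(), np.nan, np.nan, 0, False, stage),
            AuditLedger(),
        )
    return (
        PathwayResult(
            pathway=spec.serialize(),
            log_hr=fit["log_hr"],
            se=fit["se"],
            n_records_dropped=ledger.total_dropped,
            estimable=fit["estimable"],
            stage=stage,
        ),
        ledger,
    )


def sensitivity_experiment(
    raw: pd.DataFrame,
    registry: DecisionRegistry,
    primary: PathwaySpec,
    k_random: int,
    seed: int,
    plausibility: pd.DataFrame,
    followup: pd.DataFrame,
) -> list[PathwayResult]:
    """Two-stage sensitivity experiment over preparation pathways.

    Stage 1 (``stage="random"``): *k_random* pathways sampled uniformly.
    Stage 2 (``stage="primary"`` / ``"variant"``): the primary pathway plus
    every one-at-a-time variant.  Per-pathway failures are recorded as
    non-estimable results, never raised.
    """
    results = []
    for spec in sample_random_pathways(registry, k_random, seed):
        res, _ = _execute_and_fit(raw, spec, plausibility, followup, "random")
        results.append(res)
    res, _ = _execute_and_fit(raw, primary, plausibility, followup, "primary")
    results.append(res)
    for spec in one_at_a_time_variants(primary, registry):
        res, _ = _execute_and_fit(raw, spec, plausibility, followup, "variant")
        results.append(res)
    return results


def summarize_results(
    results: list[PathwayResult], hr_threshold: float | None = None
) -> dict:
    """Distribution summary over estimable pathway results.

    Median HR and SE, the HR inter-quartile range, pathways outside 1.5 x IQR
    (plus an optional absolute HR threshold), and the non-estimable count.
    """
    est = [r for r in results if r.estimable]
    if not est:
        raise ValueError("no estimable results to summarise")
    hrs = np.array([r.hr for r in est])
    ses = np.array([r.se for r in est])
    q1, q3 = np.percentile(hrs, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [r.pathway for r, h in zip(est, hrs) if h < lo or h > hi]
    if hr_threshold is not None:
        outliers += [
            r.pathway
            for r, h in zip(est, hrs)
            if h > hr_threshold and r.pathway not in outliers
        ]
    return {
        "n": len(results),
        "n_estimable": len(est),
        "n_non_estimable": len(results) - len(est),
        "median_hr": float(np.median(hrs)),
        "median_se": float(np.median(ses)),
        "hr_iqr": (float(q1), float(q3)),
        "outliers": outliers,
    }


def plot_results(results: list[PathwayResult], path: str) -> None:
    """Boxplots of the HR and SE distributions across pathways."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = [r for r in results if r.estimable]
    if not est:
        raise ValueError("no estimable results to plot")
    fig, axes = plt.subplots(1, 2, figsize=(7, 4))
    axes[0].boxplot([r.hr for r in est])
    axes[0].set_ylabel("hazard ratio")
    axes[1].boxplot([r.se for r in est])
    axes[1].set_ylabel("SE of log hazard ratio")
    for ax in axes:
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
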