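"""Synthetic CPRD-like cohorts with known exposure truth and outcome hazards.

The generator emulates the layout of a UK primary-care "therapy" extract:
one row per issued prescription with a pack-level product code, start date,
total quantity (``qty``), numeric daily dose (``ndd``) and two sparsely
populated duration fields (``numdays``, ``dose_duration``).  Product codes
are pack-level — each strength/pack size of one drug substance is a distinct
code — so a patient's scripts for one drug class scatter across a dozen
codes, as they do in real extracts.

Ground truth is a supply-consumption model: each script adds its duration to
a personal stockpile consumed one day at a time, so an early refill extends
exposure rather than overlapping it.  True exposure episodes are the maximal
intervals with positive supply.  Outcome events are drawn from a piecewise
exponential hazard: baseline off drug, baseline x exp(log-HR) while truly
exposed.

Records are first written fully consistent with the truth (``numdays`` =
true duration, ``qty`` = duration x ``ndd``, ``dose_duration`` = duration)
and then corrupted: fields are masked independently at the configured
missingness rates and replaced by out-of-bounds values at the contamination
rate.  Field masking is independent across fields and records; marginal
rates match real extracts, correlation structure is not modelled.

Two prescribing regimes are supported, with missingness defaults matching
the continuous (long-term oral hypoglycaemic-like) and intermittent
(short-course glucocorticoid-like) patterns of UK primary-care data:
continuous 12.5% / 97.2% / 99.9% missing ndd / numdays / dose_duration,
intermittent 50% / 97% / 99.2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import PLAUSIBILITY_COLUMNS, THERAPY_COLUMNS

__all__ = ["GeneratorConfig", "generate_cohort", "make_plausibility", "truth_exposure"]

#: (miss_ndd, miss_numdays, miss_dose_duration) per regime
_REGIME_MISSINGNESS = {
    "continuous": (0.125, 0.972, 0.999),
    "intermittent": (0.50, 0.97, 0.992),
}

DRUG_CLASS = "studydrug"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Missingness fields left as ``None`` take the regime's defaults.  All
    rates and probabilities are per record (or per field within record).
    """

    n_patients: int = 2000
    regime: str = "continuous"
    seed: int = 0

    # follow-up window (days from entry, uniform)
    followup_min_days: int = 365
    followup_max_days: int = 1095

    # prescribing process
    n_products: int = 12
    product_persistence: float = 0.5  # P(next script repeats previous code)
    script_duration_choices: tuple[int, ...] = (28, 56)
    script_duration_probs: tuple[float, ...] = (0.8, 0.2)
    first_script_delay_max: int = 14
    refill_gap_mean: float = 1.0  # Poisson mean, days between supply end & refill
    course_break_prob: float = 0.05  # continuous regime: chance of a treatment break
    scripts_per_course_max: int = 3  # intermittent regime: course length in scripts
    course_gap_min: int = 30
    course_gap_mean: float = 60.0
    overlap_prob: float = 0.05  # chance the next refill arrives early
    overlap_max_days: int = 7
    same_day_dup_prob: float = 0.02  # chance a script is issued as two same-day packs

    # corruption
    miss_ndd: float | None = None
    miss_numdays: float | None = None
    miss_dose_duration: float | None = None
    miss_qty: float = 0.0
    contamination: float = 0.02  # per-field chance of an out-of-bounds value

    # outcome model
    log_hr: float = math.log(2.0)
    baseline_hazard: float = 2e-4  # events per person-day off drug

    def __post_init__(self):
        if self.regime not in _REGIME_MISSINGNESS:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        defaults = _REGIME_MISSINGNESS[self.regime]
        for name, dflt in zip(("miss_ndd", "miss_numdays", "miss_dose_duration"), defaults):
            if getattr(self, name) is None:
                object.__setattr__(self, name, dflt)
        for name in ("miss_ndd", "miss_numdays", "miss_dose_duration", "miss_qty",
                     "contamination", "product_persistence", "overlap_prob",
                     "same_day_dup_prob", "course_break_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    @classmethod
    def intermittent(cls, **kwargs) -> "GeneratorConfig":
        """Intermittent-regime conditions: short courses, long gaps."""
        kwargs.setdefault("regime", "intermittent")
        kwargs.setdefault("script_duration_choices", (14, 28))
        kwargs.setdefault("script_duration_probs", (0.6, 0.4))
        kwargs.setdefault("first_script_delay_max", 180)
        kwargs.setdefault("course_gap_mean", 120.0)
        return cls(**kwargs)


def make_plausibility(config: GeneratorConfig) -> pd.DataFrame:
    """Per-product plausibility reference table matching the generator."""
    rows = []
    for i in range(config.n_products):
        ndd = float(1 + i % 3)  # fixed daily dose per pack-level product
        rows.append(
            {
                "product_code": f"P{i + 1:02d}",
                "drug_class": DRUG_CLASS,
                "qty_min": 1.0,
                "qty_max": 200.0,
                "ndd_min": 0.5,
                "ndd_max": 6.0,
                "dur_min": 1.0,
                "dur_max": 112.0,
                "default_qty": 28.0 * ndd,
                "default_ndd": ndd,
                "default_duration_days": 28.0,
            }
        )
    return pd.DataFrame(rows, columns=PLAUSIBILITY_COLUMNS)


def _simulate_scripts(config: GeneratorConfig, rng, exit_day: int):
    """One patient's script list [(start, duration, product_index), ...]."""
    t = int(rng.integers(0, config.first_script_delay_max + 1))
    scripts = []
    prod = int(rng.integers(config.n_products))
    durs = np.asarray(config.script_duration_choices)
    probs = np.asarray(config.script_duration_probs, dtype=float)
    probs = probs / probs.sum()
    scripts_left_in_course = (
        int(rng.integers(1, config.scripts_per_course_max + 1))
        if config.regime == "intermittent"
        else None
    )
    while t < exit_day:
        if rng.random() >= config.product_persistence:
            prod = int(rng.integers(config.n_products))
        dur = int(rng.choice(durs, p=probs))
        scripts.append((t, dur, prod))

        if config.regime == "intermittent":
            scripts_left_in_course -= 1
            course_ends = scripts_left_in_course == 0
            if course_ends:
                scripts_left_in_course = int(
                    rng.integers(1, config.scripts_per_course_max + 1)
                )
        else:
            course_ends = rng.random() < config.course_break_prob

        if course_ends:
            gap = config.course_gap_min + int(
                rng.exponential(max(config.course_gap_mean - config.course_gap_min, 1))
            )
        elif rng.random() < config.overlap_prob and dur > 1:
            gap = -int(rng.integers(1, min(config.overlap_max_days, dur - 1) + 1))
        else:
            gap = int(rng.poisson(config.refill_gap_mean))
        t = t + dur + gap
    return scripts


def _consume(scripts):
    """Supply-consumption truth: maximal intervals with positive stockpile."""
    intervals = []
    running_end = -np.inf
    for start, dur, _ in sorted(scripts):
        s = max(start, running_end)
        intervals.append((s, s + dur))
        running_end = s + dur
    # merge contiguous/overlapping (consumption makes them contiguous at most)
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(float(s), float(e)) for s, e in merged]


def _draw_event(rng, episodes, entry, exit_day, h0, log_hr):
    """Piecewise-exponential event day in (entry, exit_day], or None."""
    hr = math.exp(log_hr)
    target = rng.exponential(1.0)
    cum = 0.0
    t = float(entry)
    bounds = []
    for s, e in episodes:
        s, e = max(s, entry), min(e, exit_day)
        if e > s:
            bounds.append((s, e))
    pos = 0
    while t < exit_day:
        # next segment boundary and its hazard
        in_exposed = any(s <= t < e for s, e in bounds)
        nxt = exit_day
        for s, e in bounds:
            if s > t:
                nxt = min(nxt, s)
                break
            if s <= t < e:
                nxt = min(nxt, e)
                break
        haz = h0 * hr if in_exposed else h0
        seg = nxt - t
        if cum + haz * seg >= target:
            t_event = t + (target - cum) / haz
            return int(math.ceil(t_event)) if t_event > entry else int(entry) + 1
        cum += haz * seg
        t = nxt
        pos += 1
    return None


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (therapy, followup, truth) tables for one cohort.

    therapy: raw prescription rows (post-corruption).  followup: one row per
    patient with entry, exit and event_day (NaN if censored).  truth: the
    generator's ground-truth exposure episodes.
    """
    rng = np.random.default_rng(config.seed)
    plaus = make_plausibility(config)
    ndd_by_prod = plaus["default_ndd"].to_numpy()

    therapy_rows = []
    followup_rows = []
    truth_rows = []
    for pid in range(1, config.n_patients + 1):
        entry = 0
        exit_day = int(
            rng.integers(config.followup_min_days, config.followup_max_days + 1)
        )
        scripts = _simulate_scripts(config, rng, exit_day)
        truth = _consume(scripts)
        for s, e in truth:
            truth_rows.append((pid, DRUG_CLASS, s, e))

        event_day = _draw_event(
            rng, truth, entry, exit_day, config.baseline_hazard, config.log_hr
        )
        followup_rows.append(
            (pid, float(entry), float(exit_day), float(event_day) if event_day else np.nan)
        )

        # raw records, possibly split into same-day duplicates
        records = []
        for start, dur, prod in scripts:
            if dur >= 2 and rng.random() < config.same_day_dup_prob:
                d1 = dur // 2
                records.append((start, d1, prod))
                records.append((start, dur - d1, prod))
            else:
                records.append((start, dur, prod))

        for start, dur, prod in records:
            ndd = float(ndd_by_prod[prod])
            row = {
                "patient_id": pid,
                "product_code": f"P{prod + 1:02d}",
                "start": float(start),
                "qty": float(dur) * ndd,
                "ndd": ndd,
                "numdays": float(dur),
                "dose_duration": float(dur),
            }
            therapy_rows.append(row)

    therapy = pd.DataFrame(therapy_rows, columns=THERAPY_COLUMNS)
    _corrupt(therapy, plaus, config, rng)
    followup = pd.DataFrame(
        followup_rows, columns=["patient_id", "entry", "exit", "event_day"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "drug_class", "start", "stop"]
    )
    return therapy, followup, truth


def _corrupt(therapy: pd.DataFrame, plaus: pd.DataFrame, config, rng) -> None:
    """In-place corruption: implausible injection, then field masking."""
    n = len(therapy)
    hi = {
        "qty": plaus["qty_max"].iloc[0],
        "ndd": plaus["ndd_max"].iloc[0],
        "numdays": plaus["dur_max"].iloc[0],
        "dose_duration": plaus["dur_max"].iloc[0],
    }
    for fld in ("qty", "ndd", "numdays", "dose_duration"):
        if config.contamination > 0:
            bad = rng.random(n) < config.contamination
            inflate = hi[fld] * rng.uniform(5.0, 20.0, size=n)
            vals = therapy[fld].to_numpy(float)
            vals[bad] = np.round(inflate[bad], 2)
            therapy[fld] = vals
    masks = {
        "qty": config.miss_qty,
        "ndd": config.miss_ndd,
        "numdays": config.miss_numdays,
        "dose_duration": config.miss_dose_duration,
    }
    for fld, rate in masks.items():
        if rate > 0:
            gone = rng.random(n) < rate
            vals = therapy[fld].to_numpy(float)
            vals[gone] = np.nan
            therapy[fld] = vals


def truth_exposure(truth: pd.DataFrame, patient_id) -> pd.DataFrame:
    """Ground-truth episodes for one patient, disjoint and sorted."""
    rows = truth.loc[truth["patient_id"] == patient_id]
    if len(rows) == 0:
        raise KeyError(f"unknown patient {patient_id!r}")
    return rows.sort_values(["drug_class", "start"], kind="mergesort").reset_index(
        drop=True
    )
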