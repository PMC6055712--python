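"""Enumerate, sample, and execute data-preparation pathways end-to-end.

A pathway is one complete choice of assumption option at each decision node.
``run_pathway`` applies nodes 1 through 10 in fixed order — Step A cleaning,
Step B stop-date derivation, Step C episode construction — then clips the
resulting exposure episodes to follow-up, returning the timeline and a full
audit ledger.  Execution is strictly sequential; no option may inspect a
later node's choice.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import cleaning, duration, episodes
from .core import (
    AuditLedger,
    DecisionRegistry,
    PathwaySpec,
    validate_pathway,
)

__all__ = [
    "count_pathways",
    "enumerate_pathways",
    "sample_random_pathways",
    "one_at_a_time_variants",
    "run_pathway",
]


def count_pathways(registry: DecisionRegistry) -> int:
    """Number of distinct complete pathways through the registry."""
    n = 1
    for node in registry.nodes:
        n *= len(node.options)
    return n


def enumerate_pathways(registry: DecisionRegistry, limit: int = 10**5):
    """Yield every complete pathway; refuses registries beyond *limit*."""
    total = count_pathways(registry)
    if total > limit:
        raise ValueError(
            f"registry has {total} pathways, above the enumeration limit {limit}"
        )
    node_ids = [n.node_id for n in registry.nodes]
    token_lists = [n.tokens() for n in registry.nodes]
    for combo in itertools.product(*token_lists):
        yield PathwaySpec.from_dict(dict(zip(node_ids, combo)))


def sample_random_pathways(
    registry: DecisionRegistry, k: int, seed: int
) -> list[PathwaySpec]:
    """Draw *k* pathways uniformly and independently (duplicates permitted)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(k):
        mapping = {}
        for node in registry.nodes:
            toks = node.tokens()
            mapping[node.node_id] = toks[int(rng.integers(len(toks)))]
        specs.append(PathwaySpec.from_dict(mapping))
    return specs


def one_at_a_time_variants(
    primary: PathwaySpec, registry: DecisionRegistry
) -> list[PathwaySpec]:
    """All pathways differing from *primary* at exactly one node.

    One variant per non-chosen option, in node order then registry option
    order (54 - 10 = 44 variants for the default registry).
    """
    if not validate_pathway(primary, registry):
        raise ValueError("primary pathway is not valid for this registry")
    variants = []
    for node in registry.nodes:
        chosen = primary.token(node.node_id)
        for tok in node.tokens():
            if tok != chosen:
                variants.append(primary.replace(node.node_id, tok))
    return variants


def run_pathway(
    raw: pd.DataFrame,
    spec: PathwaySpec,
    plausibility: pd.DataFrame,
    followup: pd.DataFrame,
    registry: DecisionRegistry | None = None,
) -> tuple[pd.DataFrame, AuditLedger]:
    """Execute one full preparation pathway on a raw therapy table.

    Returns the final clipped exposure timeline (one row per episode:
    patient_id, drug_class, start, stop) and the complete audit ledger.
    """
    if registry is not None and not validate_pathway(spec, registry):
        raise ValueError(f"invalid pathway {spec.serialize()!r} for registry")
    ledger = AuditLedger()
    if len(raw) == 0:
        empty = pd.DataFrame(columns=episodes.EPISODE_COLUMNS)
        return empty, ledger

    tok = spec.as_dict()
    # Step A: field cleaning
    df = cleaning.clean_quantity(raw, tok[1], tok[2], plausibility, ledger)
    df = cleaning.clean_daily_dose(df, tok[3], tok[4], plausibility, ledger)
    df = cleaning.clean_duration_fields(df, tok[5], plausibility, ledger)
    # Step B: stop dates
    df = duration.assign_stop_dates(df, tok[6], ledger)
    df = duration.resolve_missing_stop(df, tok[7], plausibility, ledger)
    # Step C: episodes
    df = episodes.collapse_same_day(df, tok[8], ledger)
    eps = episodes.to_class_episodes(df, plausibility)
    eps = episodes.resolve_overlaps(eps, tok[9], ledger)
    eps = episodes.close_gaps(eps, tok[10], ledger)
    timeline = episodes.clip_to_followup(eps, followup, ledger)
    return timeline, ledger
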