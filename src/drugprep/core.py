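"""Shared domain types and conventions for prescription-exposure preparation.

Raw primary-care prescription records (one row per issued script) are turned
into a time-varying binary exposure — "currently on" vs "currently off" a drug
class — through a fixed sequence of ten decision nodes, grouped into three
steps:

* Step A (nodes 1-5): field cleaning — implausible or missing quantity
  (``qty``), numeric daily dose (``ndd``) and duration fields (``numdays``,
  ``dose_duration``) are left alone, blanked, capped or imputed.
* Step B (nodes 6-7): a stop date is derived for each prescription from one or
  several duration sources, and records whose stop date cannot be resolved are
  imputed or dropped.
* Step C (nodes 8-10): same-day duplicates are collapsed, overlapping
  prescriptions reconciled, and short gaps between successive prescriptions
  optionally bridged, yielding disjoint exposure episodes.

Each node offers several plausible assumption options; one option per node
defines a *pathway*, i.e. one complete data-preparation recipe.  The default
registry below has 10 nodes and 54 options.

Conventions used everywhere in this package:

* Dates are integer day offsets from an arbitrary epoch; no time of day.
* Episode intervals are half-open ``[start, stop)``; a one-day prescription
  has ``stop == start + 1``; length in days is ``stop - start``.
* Means of dates or day counts are rounded half-up to whole days.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("drugprep")

__all__ = [
    "Option",
    "DecisionNode",
    "DecisionRegistry",
    "PathwaySpec",
    "AuditLedger",
    "LedgerEntry",
    "default_registry",
    "validate_pathway",
    "parse_token",
    "round_half_up",
    "THERAPY_COLUMNS",
    "PLAUSIBILITY_COLUMNS",
]

#: Expected columns of a raw therapy table.  ``stop`` is absent until Step B.
THERAPY_COLUMNS = [
    "patient_id",
    "product_code",
    "start",
    "qty",
    "ndd",
    "numdays",
    "dose_duration",
]

#: Expected columns of a per-product clinical plausibility reference table.
PLAUSIBILITY_COLUMNS = [
    "product_code",
    "drug_class",
    "qty_min",
    "qty_max",
    "ndd_min",
    "ndd_max",
    "dur_min",
    "dur_max",
    "default_qty",
    "default_ndd",
    "default_duration_days",
]


def round_half_up(x):
    """Round to the nearest integer, halves away from zero upward.

    Works on scalars and arrays; NaN passes through.  This is the single
    rounding convention for derived durations and mean dates.
    """
    arr = np.floor(np.asarray(x, dtype=float) + 0.5)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(arr)
    return arr


# --------------------------------------------------------------------------
# option tokens and the decision registry
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^(\d+)([a-z])(?:\((\d+)\))?$")


@dataclass(frozen=True)
class Option:
    """One assumption option at a decision node, e.g. ``6d(30)``."""

    token: str
    node_id: int
    letter: str
    param: int | None = None

    @property
    def base(self) -> str:
        return f"{self.node_id}{self.letter}"


def parse_token(token: str) -> Option:
    """Parse an option token like ``"1b"`` or ``"10b(60)"``."""
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise ValueError(f"malformed option token: {token!r}")
    node_id, letter, param = m.groups()
    return Option(
        token=token.strip(),
        node_id=int(node_id),
        letter=letter,
        param=int(param) if param is not None else None,
    )


@dataclass(frozen=True)
class DecisionNode:
    node_id: int
    step: str  # "A", "B" or "C"
    label: str
    options: tuple[Option, ...]

    def tokens(self) -> list[str]:
        return [o.token for o in self.options]

    def has_token(self, token: str) -> bool:
        return token in self.tokens()


@dataclass(frozen=True)
class DecisionRegistry:
    """Ordered collection of decision nodes defining the assumption space."""

    nodes: tuple[DecisionNode, ...]

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids in registry")
        for n in self.nodes:
            toks = n.tokens()
            if len(set(toks)) != len(toks):
                raise ValueError(f"duplicate option tokens in node {n.node_id}")

    def node(self, node_id: int) -> DecisionNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(f"no node {node_id} in registry")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_options(self) -> int:
        return sum(len(n.options) for n in self.nodes)

    def to_yaml(self) -> str:
        data = {
            n.node_id: {"step": n.step, "label": n.label, "options": n.tokens()}
            for n in self.nodes
        }
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "DecisionRegistry":
        data = yaml.safe_load(text)
        nodes = []
        for node_id in sorted(data):
            entry = data[node_id]
            opts = tuple(parse_token(t) for t in entry["options"])
            nodes.append(
                DecisionNode(
                    node_id=int(node_id),
                    step=entry["step"],
                    label=entry.get("label", ""),
                    options=opts,
                )
            )
        return cls(nodes=tuple(nodes))


def _mk_node(node_id: int, step: str, label: str, tokens: list[str]) -> DecisionNode:
    opts = []
    for t in tokens:
        o = parse_token(t)
        if o.node_id != node_id:
            raise ValueError(f"token {t} does not belong to node {node_id}")
        opts.append(o)
    return DecisionNode(node_id=node_id, step=step, label=label, options=tuple(opts))


def default_registry() -> DecisionRegistry:
    """The default 10-node, 54-option decision registry.

    Nodes 1-5 form Step A (field cleaning), 6-7 Step B (stop-date
    derivation), 8-10 Step C (episode construction).  Parameterised options
    carry their day tolerance, e.g. ``6d(30)`` or ``10b(60)``.
    """
    nodes = (
        _mk_node(1, "A", "implausible qty", ["1a", "1b", "1c", "1d", "1e"]),
        _mk_node(2, "A", "missing qty", ["2a", "2b", "2c", "2d", "2e"]),
        _mk_node(3, "A", "implausible ndd", ["3a", "3b", "3c", "3d", "3e"]),
        _mk_node(4, "A", "missing ndd", ["4a", "4b", "4c", "4d", "4e"]),
        _mk_node(5, "A", "implausible duration fields", ["5a", "5b", "5c", "5d", "5e"]),
        _mk_node(
            6,
            "B",
            "stop-date source",
            ["6a", "6b", "6c", "6d(15)", "6d(30)", "6d(60)", "6d(90)"],
        ),
        _mk_node(7, "B", "missing stop date", ["7a", "7b", "7c", "7d", "7e"]),
        _mk_node(8, "C", "same-day duplicates", ["8a", "8b", "8c", "8d", "8e"]),
        _mk_node(9, "C", "overlapping prescriptions", ["9a", "9b", "9c", "9d", "9e"]),
        _mk_node(
            10,
            "C",
            "gaps between episodes",
            ["10a", "10b(7)", "10b(15)", "10b(30)", "10b(60)", "10b(90)", "10c"],
        ),
    )
    return DecisionRegistry(nodes=nodes)


# --------------------------------------------------------------------------
# pathway specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwaySpec:
    """One complete preparation recipe: a chosen option token per node."""

    choices: tuple[tuple[int, str], ...]  # ordered (node_id, token) pairs

    @classmethod
    def from_dict(cls, mapping: dict[int, str]) -> "PathwaySpec":
        return cls(choices=tuple(sorted(mapping.items())))

    @classmethod
    def parse(cls, text: str) -> "PathwaySpec":
        """Parse a serialized token list, e.g. ``"1b,2a,...,10b(15)"``."""
        mapping = {}
        for tok in text.split(","):
            opt = parse_token(tok)
            if opt.node_id in mapping:
                raise ValueError(f"node {opt.node_id} chosen twice in {text!r}")
            mapping[opt.node_id] = opt.token
        return cls.from_dict(mapping)

    def as_dict(self) -> dict[int, str]:
        return dict(self.choices)

    def token(self, node_id: int) -> str:
        return self.as_dict()[node_id]

    def option(self, node_id: int) -> Option:
        return parse_token(self.token(node_id))

    def serialize(self) -> str:
        return ",".join(tok for _, tok in self.choices)

    def replace(self, node_id: int, token: str) -> "PathwaySpec":
        mapping = self.as_dict()
        mapping[node_id] = token
        return PathwaySpec.from_dict(mapping)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


#: Default primary pathway used as reference in the one-at-a-time stage.
DEFAULT_PRIMARY = "1b,2a,3b,4b,5b,6c,7b,8c,9a,10b(15)"


def validate_pathway(spec: PathwaySpec, registry: DecisionRegistry) -> bool:
    """True iff *spec* chooses exactly one valid token per registry node."""
    chosen = spec.as_dict()
    if set(chosen) != {n.node_id for n in registry.nodes}:
        return False
    return all(registry.node(nid).has_token(tok) for nid, tok in chosen.items())


# --------------------------------------------------------------------------
# audit ledger
# --------------------------------------------------------------------------


@dataclass
class LedgerEntry:
    label: str  # "node1".."node10" or "clip"
    records_in: int
    records_modified: int = 0
    records_set_missing: int = 0
    records_merged: int = 0
    records_dropped: int = 0

    @property
    def records_out(self) -> int:
        return self.records_in - self.records_dropped - self.records_merged


@dataclass
class AuditLedger:
    """Per-node record accounting for one pathway execution.

    Conservation: ``records_out = records_in - records_dropped -
    records_merged`` at every node, and node *k*'s ``records_out`` equals
    node *k+1*'s ``records_in``.  "Dropped" means information discarded
    (unresolvable stop dates, later overlapping records under 9e, episodes
    outside follow-up); "merged" means records combined into one (same-day
    collapse, interval unions, gap bridging).
    """

    entries: list[LedgerEntry] = field(default_factory=list)

    def record(self, label, records_in, modified=0, set_missing=0, merged=0, dropped=0):
        entry = LedgerEntry(
            label=str(label),
            records_in=int(records_in),
            records_modified=int(modified),
            records_set_missing=int(set_missing),
            records_merged=int(merged),
            records_dropped=int(dropped),
        )
        self.entries.append(entry)
        return entry

    def get(self, label) -> LedgerEntry:
        for e in self.entries:
            if e.label == str(label):
                return e
        raise KeyError(f"no ledger entry {label!r}")

    @property
    def total_dropped(self) -> int:
        return sum(e.records_dropped for e in self.entries)

    def validate(self) -> bool:
        """Check per-entry conservation and chaining between entries.

        Chaining is only enforced across consecutive entries that count the
        same unit (prescription records through node 8; class episodes from
        node 8's output onward — node 8 output count equals node 9 input).
        """
        for e in self.entries:
            if e.records_out != e.records_in - e.records_dropped - e.records_merged:
                return False
        for prev, nxt in zip(self.entries, self.entries[1:]):
            if prev.records_out != nxt.records_in:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(e) | {"records_out": e.records_out} for e in self.entries]
        return pd.DataFrame(
            rows,
            columns=[
                "label",
                "records_in",
                "records_modified",
                "records_set_missing",
                "records_merged",
                "records_dropped",
                "records_out",
            ],
        )
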