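"""Parsing of reconstructed trees and occurrence records, and the event schedule.

The likelihood recursions never need the tree topology itself -- only the
time-ordered list of *punctual events* (leaves, sampled ancestors,
branchings, occurrences) and the number of tree lineages ``k`` crossing
each *epoch* (maximal event-free time slice).  This module turns a Newick
tree with per-sample removal annotations plus a TSV occurrence record into
that breadth-first :class:`EventSchedule`.

Conventions
-----------
* Time is age before present: t=0 now, increasing into the past; epochs are
  half-open ``(t_{h-1}, t_h]`` with event updates applied exactly at t_h.
* The youngest tip anchors t=0 unless ``present_offset`` is given (needed
  when no tip is extant, e.g. a fully extinct tree).
* Removal status is carried in ``[&rm=0/1]`` Newick comments; absent means
  unknown.  Sampled ancestors are accepted either as zero-length-branch
  child tips or as annotated degree-2 nodes, and are necessarily
  non-removed.
* A grid time may coincide with a data event (evaluation is then taken on
  the t-minus side); two distinct data events at the same time abort -- the
  model is almost-surely tie-free, so ties indicate malformed input.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import math

import dendropy
import numpy as np
import pandas as pd

from .core import ModelParams

__all__ = [
    "EventKind",
    "RemovalStatus",
    "FormatError",
    "TieError",
    "ScheduleError",
    "ReconstructedTree",
    "OccurrenceRecord",
    "EventSchedule",
    "parse_tree",
    "parse_occurrences",
    "build_schedule",
]


class FormatError(ValueError):
    """Malformed tree or occurrence input."""


class TieError(ValueError):
    """Two distinct data events at exactly the same time."""


class ScheduleError(ValueError):
    """Inconsistent event schedule (e.g. lineage count dropping below its bounds)."""


class RemovalStatus(str, enum.Enum):
    REMOVED = "removed"
    NON_REMOVED = "non_removed"
    UNKNOWN = "unknown"


class EventKind(str, enum.Enum):
    REMOVED_LEAF = "removed_leaf"
    NONREMOVED_LEAF = "nonremoved_leaf"
    UNKNOWN_LEAF = "unknown_leaf"
    SAMPLED_ANCESTOR = "sampled_ancestor"
    REMOVED_OCCURRENCE = "removed_occurrence"
    NONREMOVED_OCCURRENCE = "nonremoved_occurrence"
    UNKNOWN_OCCURRENCE = "unknown_occurrence"
    BRANCHING = "branching"
    GRID_POINT = "grid_point"
    ORIGIN = "origin"
    PRESENT = "present"


LEAF_KINDS = {EventKind.REMOVED_LEAF, EventKind.NONREMOVED_LEAF, EventKind.UNKNOWN_LEAF}
OCCURRENCE_KINDS = {
    EventKind.REMOVED_OCCURRENCE,
    EventKind.NONREMOVED_OCCURRENCE,
    EventKind.UNKNOWN_OCCURRENCE,
}
DATA_KINDS = LEAF_KINDS | OCCURRENCE_KINDS | {EventKind.SAMPLED_ANCESTOR, EventKind.BRANCHING}

_LEAF_BY_STATUS = {
    RemovalStatus.REMOVED: EventKind.REMOVED_LEAF,
    RemovalStatus.NON_REMOVED: EventKind.NONREMOVED_LEAF,
    RemovalStatus.UNKNOWN: EventKind.UNKNOWN_LEAF,
}
_OCC_BY_STATUS = {
    RemovalStatus.REMOVED: EventKind.REMOVED_OCCURRENCE,
    RemovalStatus.NON_REMOVED: EventKind.NONREMOVED_OCCURRENCE,
    RemovalStatus.UNKNOWN: EventKind.UNKNOWN_OCCURRENCE,
}


@dataclasses.dataclass
class ReconstructedTree:
    """A validated reconstructed tree reduced to its punctual events.

    ``events`` holds the strictly-positive-age tree events as
    ``(age, kind)`` pairs with kind one of the leaf kinds,
    ``sampled_ancestor`` or ``branching``; ``k0`` is the number of tips at
    present (age 0).  ``newick`` keeps the source text for round-tripping.
    """

    k0: int
    events: list[tuple[float, EventKind]]
    newick: str = ""

    @property
    def root_age(self) -> float:
        return max((a for a, _ in self.events), default=0.0)

    def counts(self) -> dict[str, int]:
        """Event counts: v sampled ancestors, w removed, y non-removed, u unknown leaves, x branchings."""
        kinds = [k for _, k in self.events]
        return {
            "v": kinds.count(EventKind.SAMPLED_ANCESTOR),
            "w": kinds.count(EventKind.REMOVED_LEAF),
            "y": kinds.count(EventKind.NONREMOVED_LEAF),
            "u": kinds.count(EventKind.UNKNOWN_LEAF),
            "x": kinds.count(EventKind.BRANCHING),
        }

    def with_unknown_status(self) -> "ReconstructedTree":
        """Copy with every leaf's removal label discarded (sampled ancestors stay non-removed)."""
        ev = [
            (a, EventKind.UNKNOWN_LEAF if k in LEAF_KINDS else k)
            for a, k in self.events
        ]
        return ReconstructedTree(self.k0, ev, self.newick)


@dataclasses.dataclass
class OccurrenceRecord:
    """Ordered record of occurrence (omega-sampling) times with removal labels."""

    times: np.ndarray
    statuses: list[RemovalStatus]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.statuses = [self.statuses[i] for i in order]
        if len(self.times) and self.times[0] < 0:
            raise FormatError("occurrence times must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def with_unknown_status(self) -> "OccurrenceRecord":
        return OccurrenceRecord(self.times.copy(), [RemovalStatus.UNKNOWN] * len(self))

    def to_tsv(self) -> str:
        code = {RemovalStatus.REMOVED: "1", RemovalStatus.NON_REMOVED: "0", RemovalStatus.UNKNOWN: "NA"}
        lines = ["time\tremoved"] + [
            f"{t:.12g}\t{code[s]}" for t, s in zip(self.times, self.statuses)
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def empty(cls) -> "OccurrenceRecord":
        return cls(np.empty(0), [])


@dataclasses.dataclass
class ScheduleEntry:
    time: float
    kind: EventKind
    is_grid: bool = False


@dataclasses.dataclass
class EventSchedule:
    """Pooled, time-ordered schedule with per-epoch lineage counts.

    ``entries[0]`` is the present (t=0) and ``entries[-1]`` the origin
    (t=t_or); ``k[h]`` is the lineage count on the open epoch
    ``(entries[h].time, entries[h+1].time)``; ``k[0]`` extends down to the
    present so ``k0 = k[0]``.
    """

    entries: list[ScheduleEntry]
    k: np.ndarray
    k0: int
    t_or: float

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.entries])

    def grid_times(self) -> list[float]:
        return [e.time for e in self.entries if e.is_grid]

    def k_at(self, t: float) -> int:
        """Lineage count on the epoch containing ``t`` (t-minus side at boundaries)."""
        times = self.times
        h = int(np.searchsorted(times, t, side="left"))  # first entry with time >= t
        if h == 0:
            return self.k0
        return int(self.k[min(h - 1, len(self.k) - 1)])


def _status_from_rm(raw) -> RemovalStatus:
    if raw is None:
        return RemovalStatus.UNKNOWN
    s = str(raw).strip().lower()
    if s in ("1", "1.0", "true", "removed"):
        return RemovalStatus.REMOVED
    if s in ("0", "0.0", "false", "non_removed", "nonremoved"):
        return RemovalStatus.NON_REMOVED
    if s in ("", "na", "nan", "none", "unknown", "?"):
        return RemovalStatus.UNKNOWN
    raise FormatError(f"unrecognised removal annotation rm={raw!r}")


def parse_tree(newick_text: str, present_offset: float = 0.0) -> ReconstructedTree:
    """Parse a Newick reconstructed tree with ``[&rm=]`` removal annotations.

    Ages are computed from branch lengths with the youngest tip at age
    ``present_offset`` (default 0, i.e. extant).  Sampled ancestors may be
    encoded as zero-length-branch child tips or as annotated degree-2
    nodes; both are normalised to punctual ``sampled_ancestor`` events.
    """
    tree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        extract_comment_metadata=True,
        suppress_internal_node_taxa=True,
    )
    root = tree.seed_node

    depth: dict[dendropy.Node, float] = {root: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        bl = nd.edge.length if nd.edge.length is not None else 0.0
        if bl < 0:
            raise FormatError(f"negative branch length {bl}")
        depth[nd] = depth[nd.parent_node] + bl

    max_depth = max(depth[lf] for lf in tree.leaf_node_iter())
    scale = max(max_depth, 1.0)
    tol = 1e-9 * scale

    def age(nd) -> float:
        a = present_offset + (max_depth - depth[nd])
        return 0.0 if abs(a) <= tol else a

    def rm_annotation(nd) -> RemovalStatus:
        for key in ("rm", "removed"):
            v = nd.annotations.get_value(key, None)
            if v is not None:
                return _status_from_rm(v)
        return RemovalStatus.UNKNOWN

    k0 = 0
    events: list[tuple[float, EventKind]] = []
    for nd in tree.preorder_node_iter():
        children = nd.child_nodes()
        if not children:  # leaf
            a = age(nd)
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            if a <= tol and not present_offset:
                k0 += 1  # present tip; removal at rho-sampling is irrelevant
            elif bl <= tol * 1e-3 and nd.parent_node is not None and len(nd.parent_node.child_nodes()) >= 2:
                # zero-length-branch child tip: sampled ancestor on the parent's branch
                if rm_annotation(nd) is RemovalStatus.REMOVED:
                    raise FormatError("a sampled ancestor cannot be labeled as removed")
                events.append((a, EventKind.SAMPLED_ANCESTOR))
            else:
                events.append((a, _LEAF_BY_STATUS[rm_annotation(nd)]))
        else:
            n_real = [c for c in children if not (len(c.child_nodes()) == 0 and (c.edge.length or 0.0) <= tol * 1e-3 and age(c) > tol)]
            if len(children) > 2:
                raise FormatError(f"non-binary internal node with {len(children)} children")
            if len(children) == 2 and len(n_real) == 2:
                events.append((age(nd), EventKind.BRANCHING))
            elif len(children) == 2 and len(n_real) == 1:
                pass  # sampled-ancestor attachment point; event recorded from the zero-length tip
            elif len(children) == 2 and len(n_real) == 0:
                raise FormatError("two zero-length sampled-ancestor tips on one node")
            else:  # single child
                if nd is root and rm_annotation(nd) is RemovalStatus.UNKNOWN and not nd.annotations.get_value("rm"):
                    continue  # bare stem above the root: not an event
                if rm_annotation(nd) is RemovalStatus.REMOVED:
                    raise FormatError("a sampled ancestor cannot be labeled as removed")
                events.append((age(nd), EventKind.SAMPLED_ANCESTOR))

    if k0 == 0 and not events:
        raise FormatError("tree contains no samples")
    events.sort(key=lambda e: e[0])
    rt = ReconstructedTree(k0=k0, events=events, newick=newick_text.strip())
    _validate_tree_counts(rt)
    return rt


def _validate_tree_counts(rt: ReconstructedTree) -> None:
    c = rt.counts()
    n_leaves = c["w"] + c["y"] + c["u"] + rt.k0
    if c["x"] != n_leaves - 1:
        raise FormatError(
            f"a rooted binary tree with {n_leaves} leaves must have {n_leaves - 1} "
            f"branchings, found {c['x']}"
        )


def parse_occurrences(tsv_text: str) -> OccurrenceRecord:
    """Parse a TSV occurrence record with columns ``time`` and ``removed`` (0/1/NA)."""
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t")
    if not {"time", "removed"} <= set(df.columns):
        raise FormatError("occurrence TSV needs columns 'time' and 'removed'")
    statuses = [
        RemovalStatus.UNKNOWN if pd.isna(v) else _status_from_rm(v)
        for v in df["removed"]
    ]
    return OccurrenceRecord(df["time"].to_numpy(dtype=float), statuses)


def build_schedule(
    tree: ReconstructedTree,
    occurrences: OccurrenceRecord | None,
    params: ModelParams,
    grid_times=(),
) -> EventSchedule:
    """Pool tree events, occurrences and grid times into an ordered schedule.

    Lineage counts per epoch are computed by a single backward sweep from
    ``k0`` (leaves increment, branchings decrement, sampled ancestors and
    occurrences leave k unchanged); the sweep must end with k=1 on the
    epoch adjoining the origin.
    """
    t_or = params.t_or
    if occurrences is None:
        occurrences = OccurrenceRecord.empty()

    data: list[tuple[float, EventKind]] = list(tree.events)
    for t, s in zip(occurrences.times, occurrences.statuses):
        if not 0.0 < t < t_or:
            raise ScheduleError(f"occurrence time {t} outside (0, t_or={t_or})")
        data.append((float(t), _OCC_BY_STATUS[s]))
    if tree.root_age >= t_or:
        raise ScheduleError(f"root age {tree.root_age} must be < t_or={t_or}")
    for a, _ in tree.events:
        if not 0.0 < a < t_or:
            raise ScheduleError(f"tree event age {a} outside (0, t_or)")

    data.sort(key=lambda e: e[0])
    for (t1, k1), (t2, k2) in zip(data, data[1:]):
        if t1 == t2:
            raise TieError(f"two data events at the same time t={t1} ({k1.value}, {k2.value})")

    grid = sorted(set(float(g) for g in grid_times))
    for g in grid:
        if not 0.0 <= g <= t_or:
            raise ScheduleError(f"grid time {g} outside [0, t_or]")

    entries = [ScheduleEntry(0.0, EventKind.PRESENT, is_grid=(len(grid) > 0 and grid[0] == 0.0))]
    gi = 1 if entries[0].is_grid else 0
    for t, kind in data:
        while gi < len(grid) and grid[gi] < t:
            entries.append(ScheduleEntry(grid[gi], EventKind.GRID_POINT, is_grid=True))
            gi += 1
        is_grid = gi < len(grid) and grid[gi] == t
        if is_grid:
            gi += 1
        entries.append(ScheduleEntry(t, kind, is_grid=is_grid))
    while gi < len(grid) and grid[gi] < t_or:
        entries.append(ScheduleEntry(grid[gi], EventKind.GRID_POINT, is_grid=True))
        gi += 1
    entries.append(ScheduleEntry(t_or, EventKind.ORIGIN, is_grid=(gi < len(grid) and grid[gi] == t_or)))

    # backward sweep for per-epoch lineage counts
    k = np.empty(len(entries) - 1, dtype=int)
    cur = tree.k0
    k[0] = cur
    for h in range(1, len(entries) - 1):
        kind = entries[h].kind
        if kind in LEAF_KINDS:
            cur += 1
        elif kind is EventKind.BRANCHING:
            cur -= 1
            if cur < 1:
                raise ScheduleError("lineage count dropped below 1 above a branching: malformed tree")
        k[h] = cur
    if k[-1] != 1:
        raise ScheduleError(f"lineage count on the oldest epoch is {k[-1]}, expected 1")
    return EventSchedule(entries=entries, k=k, k0=tree.k0, t_or=t_or)
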