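"""Event data model, CSV I/O, duplicate filtering and recall coding.

The experimental unit is a *pair*: two people take turns acting out shape
cues (the generation phase).  A day later each participant free-recalls
either their own actions (``recall_own``) or the partner's
(``recall_partner``).  Every reported action is coded against the pair's
duplicate-filtered encoding sets as a correct recall, a source error
(right action, wrong origin) or an intrusion (never generated by either
member).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

LOAD_CONDITIONS = ("none", "action_planning", "motor_execution", "verbal")
TASKS = ("recall_own", "recall_partner")
NOVEL_PREFIX = "NOVEL"

#: Default cue vocabulary: the 15 shape symbols of the standard design.
DEFAULT_SHAPES = (
    "A", "C", "F", "H", "I", "J", "K", "L", "O", "P", "T", "V", "X",
    "TRIANGLE", "EQUALS",
)

GENERATION_COLUMNS = (
    "pair_id", "participant_id", "shape_id", "action_code",
    "trial_index", "load_condition", "actor_role",
)
RECALL_COLUMNS = (
    "participant_id", "task", "shape_id", "action_code",
    "output_order", "attributed_to_target",
)


class SchemaError(ValueError):
    """A CSV does not match the documented schema."""


class IntegrityError(ValueError):
    """Records violate a structural invariant (duplicate keys, overlap...)."""


@dataclass(frozen=True)
class GenerationEvent:
    """One encoding act: a member of a pair performs an action for a cue.

    ``load_condition`` is the concurrent load imposed on the *observing*
    member during this trial; performance itself is always unloaded, so
    the label travels with the trial and is interpreted by the observer's
    analyses.
    """

    pair_id: str
    participant_id: str
    shape_id: str
    action_code: str
    trial_index: int
    load_condition: str = "none"
    role: str = "focal"
    is_duplicate_of_partner: bool = False
    is_self_repeat: bool = False

    def __post_init__(self) -> None:
        if self.load_condition not in LOAD_CONDITIONS:
            raise SchemaError(
                f"unknown load_condition {self.load_condition!r}; "
                f"expected one of {LOAD_CONDITIONS}"
            )
        if self.trial_index < 1:
            raise SchemaError("trial_index is 1-based and must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        """(shape, action): the identity of a coded action."""
        return (self.shape_id, self.action_code)


@dataclass(frozen=True)
class RecallEvent:
    """One retrieval act at test.

    ``action_code`` starting with ``NOVEL`` marks an action absent from
    the experiment's global action inventory.  ``attributed_to_target``
    is the participant's own verbal source judgement in the extended
    (report-everything-then-judge) procedure; it is always true in
    standard free report.
    """

    participant_id: str
    task: str
    shape_id: str
    action_code: str
    output_order: int
    attributed_to_target: bool = True

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise SchemaError(
                f"unknown task {self.task!r}; expected one of {TASKS}"
            )
        if self.output_order < 1:
            raise SchemaError("output_order is 1-based and must be >= 1")

    @property
    def is_novel(self) -> bool:
        return self.action_code.startswith(NOVEL_PREFIX)

    @property
    def key(self) -> tuple[str, str]:
        return (self.shape_id, self.action_code)


@dataclass(frozen=True)
class CodedCounts:
    """Per participant (x condition) tallies of the three response codes."""

    participant_id: str
    condition: str
    n_correct: int
    n_source_errors: int
    n_intrusions: int

    @property
    def n_reported(self) -> int:
        return self.n_correct + self.n_source_errors + self.n_intrusions


@dataclass(frozen=True)
class DuplicationSummary:
    """Removal bookkeeping for the pair-duplicate filter."""

    pct_self_repeats: float
    pct_partner_duplicates: float
    n_removed_actions: int


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot interpret {value!r} as a boolean")


def load_events(
    path: str | Path, phase: Literal["generation", "test"]
) -> list[GenerationEvent] | list[RecallEvent]:
    """Read one phase's CSV into typed events, validating the schema.

    Row order is preserved in ``trial_index`` / ``output_order`` (both
    1-based, as written by the generator).  A duplicated
    (participant, trial) key is an integrity error.
    """
    path = Path(path)
    if phase not in ("generation", "test"):
        raise ValueError(f"unknown phase {phase!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if phase == "generation":
        _require_columns(df, GENERATION_COLUMNS, str(path))
        events_g: list[GenerationEvent] = [
            GenerationEvent(
                pair_id=row.pair_id,
                participant_id=row.participant_id,
                shape_id=row.shape_id,
                action_code=row.action_code,
                trial_index=int(row.trial_index),
                load_condition=row.load_condition,
                role=row.actor_role,
            )
            for row in df.itertuples(index=False)
        ]
        keys = [(e.participant_id, e.trial_index) for e in events_g]
        if len(keys) != len(set(keys)):
            raise IntegrityError(
                f"{path}: duplicate (participant_id, trial_index) rows"
            )
        return events_g

    _require_columns(df, RECALL_COLUMNS, str(path))
    events_r: list[RecallEvent] = [
        RecallEvent(
            participant_id=row.participant_id,
            task=row.task,
            shape_id=row.shape_id,
            action_code=row.action_code,
            output_order=int(row.output_order),
            attributed_to_target=_as_bool(row.attributed_to_target),
        )
        for row in df.itertuples(index=False)
    ]
    keys = [(e.participant_id, e.output_order) for e in events_r]
    if len(keys) != len(set(keys)):
        raise IntegrityError(f"{path}: duplicate (participant_id, output_order) rows")
    return events_r


def write_generation_csv(events: Iterable[GenerationEvent], path: str | Path) -> None:
    rows = [
        {
            "pair_id": e.pair_id,
            "participant_id": e.participant_id,
            "shape_id": e.shape_id,
            "action_code": e.action_code,
            "trial_index": e.trial_index,
            "load_condition": e.load_condition,
            "actor_role": e.role,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=list(GENERATION_COLUMNS)).to_csv(path, index=False)


def write_recall_csv(events: Iterable[RecallEvent], path: str | Path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "task": e.task,
            "shape_id": e.shape_id,
            "action_code": e.action_code,
            "output_order": e.output_order,
            "attributed_to_target": e.attributed_to_target,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=list(RECALL_COLUMNS)).to_csv(path, index=False)


def filter_pair_duplicates(
    events: Sequence[GenerationEvent],
) -> tuple[list[GenerationEvent], DuplicationSummary]:
    """Remove within-pair duplicated actions from the encoding sets.

    Self-repeats keep the first occurrence; any (shape, action) performed
    by *both* members of the pair is removed from the retained encoding
    sets of both members.  Percentages are reported relative to the total
    number of generated actions; a duplication is attributed to the event
    that came second in the pair's interleaved trial order.
    """
    if not events:
        return [], DuplicationSummary(0.0, 0.0, 0)
    pair_ids = {e.pair_id for e in events}
    if len(pair_ids) != 1:
        raise IntegrityError(
            f"filter_pair_duplicates expects one pair, got {sorted(pair_ids)}"
        )
    # Interleaved chronological order: trial t of every member precedes
    # trial t+1 of any member; the focal member acts first within a round.
    ordered = sorted(events, key=lambda e: (e.trial_index, e.role != "focal"))

    seen_by_member: dict[str, set[tuple[str, str]]] = {}
    annotated: list[GenerationEvent] = []
    n_self = 0
    n_partner = 0
    for e in ordered:
        own = seen_by_member.setdefault(e.participant_id, set())
        others = set().union(
            *(s for pid, s in seen_by_member.items() if pid != e.participant_id)
        ) if len(seen_by_member) > 1 else set()
        is_self = e.key in own
        is_partner = e.key in others
        n_self += is_self
        n_partner += is_partner
        own.add(e.key)
        annotated.append(
            replace(e, is_self_repeat=is_self, is_duplicate_of_partner=is_partner)
        )

    # Keys performed by more than one member are dropped for everyone.
    members: dict[tuple[str, str], set[str]] = {}
    for e in annotated:
        members.setdefault(e.key, set()).add(e.participant_id)
    shared = {k for k, who in members.items() if len(who) > 1}

    retained: list[GenerationEvent] = []
    first_seen: set[tuple[str, tuple[str, str]]] = set()
    for e in annotated:
        if e.key in shared:
            continue
        tag = (e.participant_id, e.key)
        if tag in first_seen:
            continue  # later self-repeat of a retained action
        first_seen.add(tag)
        retained.append(e)

    total = len(ordered)
    summary = DuplicationSummary(
        pct_self_repeats=100.0 * n_self / total,
        pct_partner_duplicates=100.0 * n_partner / total,
        n_removed_actions=total - len(retained),
    )
    return retained, summary


def apply_extended_recall_filter(
    events: Sequence[RecallEvent], mode: Literal["free_report", "extended"]
) -> tuple[list[RecallEvent], list[RecallEvent]]:
    """Split recall events into (reported, withheld) sets.

    In ``extended`` mode only events the participant judged to come from
    the target source count as reported; rejected events are returned
    separately for diagnostics and never tallied downstream.  In
    ``free_report`` mode everything counts as reported.
    """
    if mode == "free_report":
        return list(events), []
    if mode != "extended":
        raise ValueError(f"unknown mode {mode!r}")
    reported = [e for e in events if e.attributed_to_target]
    withheld = [e for e in events if not e.attributed_to_target]
    return reported, withheld


def encoding_sets(
    filtered: Sequence[GenerationEvent], participant_id: str
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """(own, partner) retained encoding sets for one member of a pair."""
    own = {e.key for e in filtered if e.participant_id == participant_id}
    partner = {e.key for e in filtered if e.participant_id != participant_id}
    return own, partner


def code_recall_events(
    recall: Sequence[RecallEvent],
    own_set: set[tuple[str, str]],
    partner_set: set[tuple[str, str]],
    task: str,
    condition: str = "pooled",
) -> tuple[CodedCounts, list[tuple[RecallEvent, str]]]:
    """Code each reported action as correct / source_error / intrusion.

    For ``recall_own`` a reported action in the participant's own
    retained set is correct, one in the partner's set is a source error
    and anything else (including out-of-inventory actions) is an
    intrusion; roles mirror for ``recall_partner``.  Re-reports of the
    same (shape, action) by a participant count once (first occurrence).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if own_set & partner_set:
        raise IntegrityError(
            "own and partner encoding sets overlap; run filter_pair_duplicates first"
        )
    target, nontarget = (
        (own_set, partner_set) if task == "recall_own" else (partner_set, own_set)
    )
    participants = {e.participant_id for e in recall}
    if len(participants) > 1:
        raise IntegrityError(f"events from several participants: {sorted(participants)}")

    labels: list[tuple[RecallEvent, str]] = []
    seen: set[tuple[str, str]] = set()
    n_correct = n_source = n_intrusion = 0
    for e in sorted(recall, key=lambda e: e.output_order):
        if e.key in seen:
            labels.append((e, "repeat"))
            continue
        seen.add(e.key)
        if not e.is_novel and e.key in target:
            labels.append((e, "correct"))
            n_correct += 1
        elif not e.is_novel and e.key in nontarget:
            labels.append((e, "source_error"))
            n_source += 1
        else:
            labels.append((e, "intrusion"))
            n_intrusion += 1

    pid = recall[0].participant_id if recall else ""
    counts = CodedCounts(
        participant_id=pid,
        condition=condition,
        n_correct=n_correct,
        n_source_errors=n_source,
        n_intrusions=n_intrusion,
    )
    return counts, labels
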