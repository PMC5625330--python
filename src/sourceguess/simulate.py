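"""Generative model of the paired generation/recall experiment.

Two people take turns acting out shape cues (by default 15 cues, 3
exemplars each, i.e. 45 performed and 45 observed actions per member).
Each cue has a population of 20–40 distinct coded actions with a skewed
popularity profile; members occasionally duplicate their own or their
partner's actions.  At test each participant retrieves encoded items
with source noise and pads output with popularity-driven guesses — the
two error routes (genuine source confusion vs. guessing) are separate
parameters, so the guessing-null analysis can be validated against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .coding import (
    DEFAULT_SHAPES,
    GenerationEvent,
    RecallEvent,
    write_generation_csv,
    write_recall_csv,
)

__all__ = [
    "ActionSpaceConfig",
    "EncodingConfig",
    "RecallConfig",
    "ExperimentConfig",
    "ActionSpace",
    "SyntheticDataset",
    "make_action_space",
    "simulate_generation_phase",
    "simulate_test_phase",
    "simulate_experiment",
    "write_dataset",
]


@dataclass(frozen=True)
class ActionSpaceConfig:
    """Population of coded actions available per shape cue."""

    n_shapes: int = 15
    support_range: tuple[int, int] = (20, 40)
    popularity: Literal["zipf", "dirichlet"] = "zipf"
    popularity_param: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.support_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid support_range {self.support_range}")
        if self.n_shapes < 1:
            raise ValueError("need at least one shape")


@dataclass(frozen=True)
class EncodingConfig:
    """Generation-phase behavior of a pair.

    Duplication probabilities default to the low rates typical of
    confederate-run sessions (~0.5% self-repeats, ~1.3% partner
    copies); naive pairs under load run an order of magnitude higher.
    ``load_encoding_penalty`` multiplies the observer's retrieval
    probability for actions observed under a concurrent load.
    """

    exemplars_per_shape: int = 3
    p_self_repeat: float = 0.005
    p_partner_duplicate: float = 0.013
    load_schedule: Mapping[str, str] | None = None
    load_encoding_penalty: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_self_repeat, self.p_partner_duplicate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 < self.load_encoding_penalty <= 1.0:
            raise ValueError("load_encoding_penalty must be in (0, 1]")


@dataclass(frozen=True)
class RecallConfig:
    """Test-phase behavior: genuine retrieval plus guessing.

    ``p_source_confusion`` is the probability a retrieved item is
    attributed to the wrong source — the memory error the analysis is
    after.  Guessing pads each shape with Poisson(``guess_rate``)
    popularity-driven items, a fraction of which are true novels
    (outside the experiment's inventory).  ``monitoring_strictness``
    only applies in extended-report mode: a wrong-source candidate is
    caught and withheld with that probability.
    """

    p_retrieve_own: float = 0.55
    p_retrieve_partner: float = 0.40
    p_source_confusion: float = 0.15
    guess_rate: float = 0.5
    p_guess_outside_inventory: float = 0.10
    monitoring_strictness: float = 0.8

    def __post_init__(self) -> None:
        for p in (
            self.p_retrieve_own, self.p_retrieve_partner, self.p_source_confusion,
            self.p_guess_outside_inventory, self.monitoring_strictness,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.guess_rate < 0:
            raise ValueError("guess_rate must be >= 0")


@dataclass(frozen=True)
class ExperimentConfig:
    space: ActionSpaceConfig = field(default_factory=ActionSpaceConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    recall: RecallConfig = field(default_factory=RecallConfig)
    n_pairs: int = 20
    mode: Literal["free_report", "extended"] = "free_report"
    task: Literal["both", "recall_own", "recall_partner"] = "both"
    seed: int = 0


@dataclass(frozen=True)
class ActionSpace:
    shapes: tuple[str, ...]
    supports: Mapping[str, tuple[str, ...]]
    popularity: Mapping[str, np.ndarray]

    def inventory(self) -> set[tuple[str, str]]:
        return {(s, c) for s in self.shapes for c in self.supports[s]}


@dataclass
class SyntheticDataset:
    generation: list[GenerationEvent]
    recall: list[RecallEvent]
    truth: dict


def _popularity_vector(
    n: int, kind: str, param: float, rng: np.random.Generator
) -> np.ndarray:
    if kind == "zipf":
        w = 1.0 / np.arange(1, n + 1, dtype=float) ** param
    elif kind == "dirichlet":
        w = rng.dirichlet(np.full(n, param))
    else:
        raise ValueError(f"unknown popularity kind {kind!r}")
    return w / w.sum()


def make_action_space(
    config: ActionSpaceConfig, rng: np.random.Generator | None = None
) -> ActionSpace:
    """Draw the per-shape action inventory and popularity profile."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shapes = tuple(
        DEFAULT_SHAPES[i] if i < len(DEFAULT_SHAPES) else f"SHAPE{i:02d}"
        for i in range(config.n_shapes)
    )
    lo, hi = config.support_range
    supports: dict[str, tuple[str, ...]] = {}
    popularity: dict[str, np.ndarray] = {}
    for shape in shapes:
        size = int(rng.integers(lo, hi + 1))
        supports[shape] = tuple(f"{shape}_a{j:02d}" for j in range(size))
        popularity[shape] = _popularity_vector(
            size, config.popularity, config.popularity_param, rng
        )
    return ActionSpace(shapes=shapes, supports=supports, popularity=popularity)


def _weighted_pick(
    codes: Sequence[str], probs: np.ndarray, allowed: set[str],
    rng: np.random.Generator,
) -> str:
    mask = np.array([c in allowed for c in codes])
    p = probs * mask
    total = p.sum()
    if total <= 0:
        raise RuntimeError("no eligible action codes left")
    return str(rng.choice(np.asarray(codes, dtype=object), p=p / total))


def simulate_generation_phase(
    space: ActionSpace,
    enc: EncodingConfig,
    rng: np.random.Generator,
    pair_id: str = "pair000",
    member_ids: tuple[str, str] = ("p000", "p001"),
) -> list[GenerationEvent]:
    """One pair's interleaved generation phase.

    Members alternate within each cue; a fresh action is drawn from the
    popularity profile restricted to codes the pair has not used, except
    that with ``p_self_repeat`` (``p_partner_duplicate``) the member
    instead re-draws from their own (the partner's) used set, producing
    a labeled duplication error.
    """
    smallest = min(len(space.supports[s]) for s in space.shapes)
    if 2 * enc.exemplars_per_shape > smallest:
        raise ValueError(
            f"{enc.exemplars_per_shape} exemplars x 2 members exceeds the "
            f"smallest support ({smallest})"
        )
    schedule = dict(enc.load_schedule or {})
    events: list[GenerationEvent] = []
    trial = {member_ids[0]: 0, member_ids[1]: 0}
    for shape in space.shapes:
        codes = space.supports[shape]
        probs = space.popularity[shape]
        used: dict[str, set[str]] = {member_ids[0]: set(), member_ids[1]: set()}
        load = schedule.get(shape, "none")
        for _ in range(enc.exemplars_per_shape):
            for who, role in zip(member_ids, ("focal", "partner")):
                other = member_ids[1] if who == member_ids[0] else member_ids[0]
                u = rng.random()
                if u < enc.p_self_repeat and used[who]:
                    code = _weighted_pick(codes, probs, used[who], rng)
                elif (
                    u < enc.p_self_repeat + enc.p_partner_duplicate
                    and used[other] - used[who]
                ):
                    code = _weighted_pick(codes, probs, used[other] - used[who], rng)
                else:
                    fresh = set(codes) - used[who] - used[other]
                    code = _weighted_pick(codes, probs, fresh, rng)
                used[who].add(code)
                trial[who] += 1
                events.append(
                    GenerationEvent(
                        pair_id=pair_id,
                        participant_id=who,
                        shape_id=shape,
                        action_code=code,
                        trial_index=trial[who],
                        load_condition=load,
                        role=role,
                    )
                )
    return events


def simulate_test_phase(
    gen_events: Sequence[GenerationEvent],
    participant_id: str,
    space: ActionSpace,
    rec: RecallConfig,
    task: str,
    mode: Literal["free_report", "extended"],
    rng: np.random.Generator,
    load_penalty: float = 1.0,
) -> list[RecallEvent]:
    """One participant's test phase for their assigned retrieval task.

    Every encoded item is retrieved independently; retrieved items are
    attributed to the wrong source with ``p_source_confusion`` and
    reported when the attributed source matches the task (in extended
    mode everything retrieved is performed and the source judgement is
    recorded; a wrong-source candidate is withheld with
    ``monitoring_strictness``).  Guesses per shape are Poisson and
    popularity-driven, excluding codes already output for that shape.
    """
    if task not in ("recall_own", "recall_partner"):
        raise ValueError(f"unknown task {task!r}")
    own_items: dict[tuple[str, str], str] = {}
    partner_items: dict[tuple[str, str], str] = {}
    for e in gen_events:
        bucket = own_items if e.participant_id == participant_id else partner_items
        bucket.setdefault(e.key, e.load_condition)
    target_source = "self" if task == "recall_own" else "partner"

    emitted: list[tuple[str, str, bool]] = []  # (shape, code, attributed_to_target)
    output_per_shape: dict[str, set[str]] = {}

    for (shape, code), load in own_items.items():
        if rng.random() >= rec.p_retrieve_own:
            continue
        confused = rng.random() < rec.p_source_confusion
        attributed = "partner" if confused else "self"
        _emit_retrieved(
            emitted, output_per_shape, shape, code, attributed, "self",
            target_source, mode, rec, rng,
        )
    for (shape, code), load in partner_items.items():
        p = rec.p_retrieve_partner * (load_penalty if load != "none" else 1.0)
        if rng.random() >= p:
            continue
        confused = rng.random() < rec.p_source_confusion
        attributed = "self" if confused else "partner"
        _emit_retrieved(
            emitted, output_per_shape, shape, code, attributed, "partner",
            target_source, mode, rec, rng,
        )

    novel_counter = 0
    for shape in space.shapes:
        n_guess = int(rng.poisson(rec.guess_rate))
        codes = space.supports[shape]
        probs = space.popularity[shape]
        for _ in range(n_guess):
            already = output_per_shape.setdefault(shape, set())
            remaining = set(codes) - already
            if rng.random() < rec.p_guess_outside_inventory or not remaining:
                novel_counter += 1
                code = f"NOVEL:{shape}_{novel_counter:03d}"
            else:
                code = _weighted_pick(codes, probs, remaining, rng)
            already.add(code)
            emitted.append((shape, code, True))

    return [
        RecallEvent(
            participant_id=participant_id,
            task=task,
            shape_id=shape,
            action_code=code,
            output_order=i + 1,
            attributed_to_target=attributed,
        )
        for i, (shape, code, attributed) in enumerate(emitted)
    ]


def _emit_retrieved(
    emitted: list,
    output_per_shape: dict[str, set[str]],
    shape: str,
    code: str,
    attributed: str,
    true_source: str,
    target_source: str,
    mode: str,
    rec: RecallConfig,
    rng: np.random.Generator,
) -> None:
    candidate = attributed == target_source
    if mode == "free_report":
        if candidate:
            emitted.append((shape, code, True))
            output_per_shape.setdefault(shape, set()).add(code)
        return
    # extended report: everything retrieved is performed; the verbal
    # source judgement can still catch a wrong-source candidate.
    as_target = candidate
    if candidate and true_source != target_source:
        if rng.random() < rec.monitoring_strictness:
            as_target = False
    emitted.append((shape, code, as_target))
    output_per_shape.setdefault(shape, set()).add(code)


def simulate_experiment(config: ExperimentConfig) -> SyntheticDataset:
    """End-to-end synthetic dataset in the pipeline's CSV schemas.

    Deterministic under ``config.seed``; the ground-truth parameters and
    seed travel in the dataset's ``truth`` sidecar.
    """
    rng = np.random.default_rng(config.seed)
    space = make_action_space(config.space, rng)
    generation: list[GenerationEvent] = []
    recall: list[RecallEvent] = []
    penalty = config.encoding.load_encoding_penalty
    for i in range(config.n_pairs):
        pair_id = f"pair{i:03d}"
        members = (f"p{2 * i:03d}", f"p{2 * i + 1:03d}")
        pair_events = simulate_generation_phase(
            space, config.encoding, rng, pair_id=pair_id, member_ids=members
        )
        generation.extend(pair_events)
        if config.task == "both":
            tasks = ("recall_own", "recall_partner")
        else:
            tasks = (config.task, config.task)
        for who, task in zip(members, tasks):
            recall.extend(
                simulate_test_phase(
                    pair_events, who, space, config.recall, task,
                    config.mode, rng, load_penalty=penalty,
                )
            )
    truth = {
        "seed": config.seed,
        "n_pairs": config.n_pairs,
        "mode": config.mode,
        "task": config.task,
        "space": asdict(config.space),
        "encoding": {
            **asdict(config.encoding),
            "load_schedule": dict(config.encoding.load_schedule or {}),
        },
        "recall": asdict(config.recall),
        "support_sizes": {s: len(space.supports[s]) for s in space.shapes},
    }
    return SyntheticDataset(generation=generation, recall=recall, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write generation.csv, recall.csv and the truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "generation": outdir / "generation.csv",
        "recall": outdir / "recall.csv",
        "truth": outdir / "truth.json",
    }
    write_generation_csv(dataset.generation, paths["generation"])
    write_recall_csv(dataset.recall, paths["recall"])
    paths["truth"].write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
    return paths
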