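"""Monte Carlo guessing baseline for source errors in free recall.

The null model: at test a participant does not retrieve anything but
generates actions "on the fly", drawing — without replacement — from the
population frequency distribution of actions for each shape cue.  Some
of those guesses coincide with the partner's actions (simulated source
errors), some with nobody's (simulated novel actions).  Averaging the
per-replicate fraction

    ratio = source_errors_sampled / (source_errors_sampled + novel_sampled)

over replicates gives the probability that a guessed *error* is a source
error.  Scaling the participant's observed intrusion count by the odds
``ratio / (1 - ratio)`` then predicts how many of their observed source
errors guessing alone would produce:

    predicted_source_errors = n_intrusions_observed * ratio / (1 - ratio)

Both the stochastic estimator and an exact enumeration oracle (small
supports) are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coding import GenerationEvent

__all__ = [
    "FrequencyNorms",
    "GuessRepOutcome",
    "GuessingPrediction",
    "build_frequency_norms",
    "draw_guess_set",
    "enumerate_guess_distribution",
    "exact_guessing_ratio",
    "simulate_guessing_ratio",
    "predict_source_errors",
    "predict_participant",
]

_PROB_TOL = 1e-12

Key = tuple[str, str]


@dataclass(frozen=True)
class FrequencyNorms:
    """Per-shape probability distribution over coded actions.

    The support for a shape is exactly the set of actions generated for
    it anywhere in the experiment; probabilities are strictly positive
    and sum to one per shape.
    """

    probs: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for shape, dist in self.probs.items():
            if not dist:
                raise ValueError(f"shape {shape!r} has empty support")
            total = math.fsum(dist.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"shape {shape!r}: probabilities sum to {total}")
            if any(p <= 0 for p in dist.values()):
                raise ValueError(f"shape {shape!r}: non-positive probability")

    @property
    def shapes(self) -> list[str]:
        return list(self.probs)

    def support(self, shape_id: str) -> list[str]:
        return list(self.probs[shape_id])

    def support_size(self, shape_id: str) -> int:
        return len(self.probs[shape_id])

    def arrays(self, shape_id: str) -> tuple[list[str], np.ndarray]:
        codes = list(self.probs[shape_id])
        p = np.array([self.probs[shape_id][c] for c in codes], dtype=float)
        return codes, p


@dataclass(frozen=True)
class GuessRepOutcome:
    """Category tallies for one sampling replicate, summed over shapes."""

    n_matched_self: int
    n_matched_partner: int
    n_novel: int
    n_source_errors: int


@dataclass(frozen=True)
class GuessingPrediction:
    """Per-participant ratio estimate and predicted source errors."""

    participant_id: str
    ratio: float
    predicted_source_errors: float
    n_intrusions_observed: int
    n_reps: int
    n_degenerate_reps: int
    seed: int
    all_degenerate: bool = False
    ratio_saturated: bool = False


def build_frequency_norms(events: Sequence[GenerationEvent]) -> FrequencyNorms:
    """Estimate frequency norms from every generation event.

    Each occurrence counts, including duplicated actions: the norms
    describe the population action space, not the filtered encoding sets.
    Shapes with zero events are simply absent (warned about by callers
    that expected them).
    """
    counts: dict[str, dict[str, int]] = {}
    for e in events:
        counts.setdefault(e.shape_id, {}).setdefault(e.action_code, 0)
        counts[e.shape_id][e.action_code] += 1
    if not counts:
        raise ValueError("no generation events")
    probs = {
        shape: {a: c / sum(dist.values()) for a, c in dist.items()}
        for shape, dist in counts.items()
    }
    return FrequencyNorms(probs)


def draw_guess_set(
    norms: FrequencyNorms, shape_id: str, k: int, rng: np.random.Generator
) -> set[str]:
    """Draw ``k`` distinct actions for a shape, popularity-weighted.

    Sampling is without replacement with renormalization of the
    remaining mass after every draw, realized by the exponential-race
    construction (smallest k of Exp(1)/p_i), which has exactly that
    distribution.
    """
    codes, p = norms.arrays(shape_id)
    if k > len(codes):
        raise ValueError(
            f"k={k} exceeds support size {len(codes)} of shape {shape_id!r}"
        )
    if k == 0:
        return set()
    keys = rng.standard_exponential(len(codes)) / p
    idx = np.argpartition(keys, k - 1)[:k]
    return {codes[i] for i in idx}


@dataclass(frozen=True)
class EnumeratedGuess:
    """Exact distribution of draw_guess_set on a small support."""

    shape_id: str
    k: int
    subset_probs: Mapping[frozenset, float]
    inclusion_probs: Mapping[str, float]

    def expected_counts(self, own: set[Key], partner: set[Key]) -> dict[str, float]:
        """Expected matched_self / matched_partner / novel per draw set."""
        shape = self.shape_id
        out = {"matched_self": 0.0, "matched_partner": 0.0, "novel": 0.0}
        for code, prob in self.inclusion_probs.items():
            if (shape, code) in own:
                out["matched_self"] += prob
            elif (shape, code) in partner:
                out["matched_partner"] += prob
            else:
                out["novel"] += prob
        return out


def enumerate_guess_distribution(
    norms: FrequencyNorms, shape_id: str, k: int, max_support: int = 12
) -> EnumeratedGuess:
    """Brute-force oracle: exact law of the without-replacement draw.

    Sums sequence probabilities over all ordered draws via a
    subset-recursion (the probability of exhausting a subset S equals
    the sum over its possible last elements).  Limited to small supports.
    """
    codes, p = norms.arrays(shape_id)
    n = len(codes)
    if n > max_support:
        raise ValueError(f"support size {n} exceeds enumeration limit {max_support}")
    if k > n:
        raise ValueError(f"k={k} exceeds support size {n}")
    # f[mask] = P(first popcount(mask) draws are exactly that subset)
    f = {0: 1.0}
    for size in range(k):
        nxt: dict[int, float] = {}
        for mask, prob in f.items():
            if bin(mask).count("1") != size:
                continue
            remaining_mass = 1.0 - sum(p[i] for i in range(n) if mask >> i & 1)
            for i in range(n):
                if mask >> i & 1:
                    continue
                new = mask | (1 << i)
                nxt[new] = nxt.get(new, 0.0) + prob * p[i] / remaining_mass
        f.update(nxt)
    subset_probs = {
        frozenset(codes[i] for i in range(n) if mask >> i & 1): prob
        for mask, prob in f.items()
        if bin(mask).count("1") == k
    }
    inclusion = {c: 0.0 for c in codes}
    for subset, prob in subset_probs.items():
        for c in subset:
            inclusion[c] += prob
    return EnumeratedGuess(shape_id, k, subset_probs, inclusion)


def exact_guessing_ratio(
    norms: FrequencyNorms,
    reported_counts: Mapping[str, int],
    own_set: set[Key],
    partner_set: set[Key],
    task: str,
) -> tuple[float, float]:
    """Exact value the Monte Carlo ratio estimates, on small supports.

    Convolves the per-shape joint law of (source errors, novel) over all
    shapes and returns ``(E[se/(se+novel) | se+novel > 0],
    P(se+novel = 0))`` — the estimand of the replicate-mean ratio with
    degenerate replicates excluded.
    """
    nontarget = partner_set if task == "recall_own" else own_set
    joint: dict[tuple[int, int], float] = {(0, 0): 1.0}
    for shape, k in reported_counts.items():
        if k == 0:
            continue
        enum = enumerate_guess_distribution(norms, shape, k)
        local: dict[tuple[int, int], float] = {}
        for subset, prob in enum.subset_probs.items():
            se = sum(1 for c in subset if (shape, c) in nontarget)
            nov = sum(
                1 for c in subset
                if (shape, c) not in own_set and (shape, c) not in partner_set
            )
            key = (se, nov)
            local[key] = local.get(key, 0.0) + prob
        new: dict[tuple[int, int], float] = {}
        for (se0, nov0), p0 in joint.items():
            for (se1, nov1), p1 in local.items():
                key = (se0 + se1, nov0 + nov1)
                new[key] = new.get(key, 0.0) + p0 * p1
        joint = new
    p_degenerate = joint.get((0, 0), 0.0)
    if p_degenerate >= 1.0 - _PROB_TOL:
        return math.nan, 1.0
    num = sum(p * se / (se + nov) for (se, nov), p in joint.items() if se + nov > 0)
    return num / (1.0 - p_degenerate), p_degenerate


def simulate_guessing_ratio(
    reported_counts: Mapping[str, int],
    own_set: set[Key],
    partner_set: set[Key],
    norms: FrequencyNorms,
    task: str,
    n_reps: int = 500,
    rng: np.random.Generator | None = None,
    keep_outcomes: bool = True,
) -> tuple[float, int, list[GuessRepOutcome]]:
    """Replicate the guessed test phase and estimate the error ratio.

    Per replicate, for every shape the participant's reported count of
    actions is drawn from the norms without replacement and each sampled
    action is classified against the duplicate-filtered encoding sets.
    Source errors are matches of the non-target source.  Replicates with
    no simulated errors at all (0/0) carry no information about the
    ratio and are excluded from the mean; their count is returned.

    Returns ``(ratio, n_degenerate_reps, outcomes)``; ratio is NaN when
    every replicate was degenerate.
    """
    if task not in ("recall_own", "recall_partner"):
        raise ValueError(f"unknown task {task!r}")
    if rng is None:
        rng = np.random.default_rng()
    se_total = np.zeros(n_reps, dtype=np.int64)
    self_total = np.zeros(n_reps, dtype=np.int64)
    partner_total = np.zeros(n_reps, dtype=np.int64)
    novel_total = np.zeros(n_reps, dtype=np.int64)
    for shape, k in reported_counts.items():
        if k == 0:
            continue
        codes, p = norms.arrays(shape)
        n = len(codes)
        if k > n:
            raise ValueError(
                f"reported count {k} exceeds support size {n} for shape {shape!r}"
            )
        own_mask = np.array([(shape, c) in own_set for c in codes])
        partner_mask = np.array([(shape, c) in partner_set for c in codes])
        keys = rng.standard_exponential((n_reps, n)) / p
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        self_total += own_mask[idx].sum(axis=1)
        partner_total += partner_mask[idx].sum(axis=1)
        novel_total += (~own_mask[idx] & ~partner_mask[idx]).sum(axis=1)
    se_total = partner_total if task == "recall_own" else self_total

    denom = se_total + novel_total
    retained = denom > 0
    n_degenerate = int(n_reps - retained.sum())
    if retained.any():
        ratio = float(np.mean(se_total[retained] / denom[retained]))
    else:
        ratio = math.nan
    outcomes: list[GuessRepOutcome] = []
    if keep_outcomes:
        outcomes = [
            GuessRepOutcome(
                n_matched_self=int(self_total[i]),
                n_matched_partner=int(partner_total[i]),
                n_novel=int(novel_total[i]),
                n_source_errors=int(se_total[i]),
            )
            for i in range(n_reps)
        ]
    return ratio, n_degenerate, outcomes


def predict_source_errors(ratio: float, n_intrusions_observed: int) -> float:
    """Scale the observed intrusion count by the guessing odds."""
    if not 0.0 <= ratio < 1.0:
        raise ValueError(f"ratio must be in [0, 1), got {ratio}")
    if n_intrusions_observed < 0:
        raise ValueError("intrusion count must be >= 0")
    return n_intrusions_observed * ratio / (1.0 - ratio)


def predict_participant(
    participant_id: str,
    reported_counts: Mapping[str, int],
    n_intrusions_observed: int,
    own_set: set[Key],
    partner_set: set[Key],
    norms: FrequencyNorms,
    task: str,
    n_reps: int = 500,
    seed: int = 0,
) -> GuessingPrediction:
    """Full per-participant pipeline: ratio estimate plus prediction.

    Reported counts larger than a shape's support are truncated with a
    warning (the simulated participant cannot guess more distinct
    actions than exist for the cue).  A saturated ratio (1.0: novel
    outcomes impossible) and the all-degenerate case are flagged; both
    yield a guarded prediction (NaN and 0.0 respectively).
    """
    counts = dict(reported_counts)
    for shape, k in counts.items():
        cap = norms.support_size(shape)
        if k > cap:
            warnings.warn(
                f"participant {participant_id}: reported {k} actions for shape "
                f"{shape!r} but its support has {cap}; truncating"
            )
            counts[shape] = cap
    rng = np.random.default_rng(seed)
    ratio, n_degenerate, _ = simulate_guessing_ratio(
        counts, own_set, partner_set, norms, task,
        n_reps=n_reps, rng=rng, keep_outcomes=False,
    )
    all_degenerate = math.isnan(ratio)
    saturated = (not all_degenerate) and ratio >= 1.0
    if all_degenerate:
        warnings.warn(
            f"participant {participant_id}: all {n_reps} replicates degenerate; "
            "treating predicted source errors as 0"
        )
        predicted = 0.0
        ratio_out = math.nan
    elif saturated:
        warnings.warn(
            f"participant {participant_id}: guessing ratio saturated at 1 "
            "(no novel outcome possible); prediction undefined"
        )
        predicted = math.nan
        ratio_out = ratio
    else:
        predicted = predict_source_errors(ratio, n_intrusions_observed)
        ratio_out = ratio
    return GuessingPrediction(
        participant_id=participant_id,
        ratio=ratio_out,
        predicted_source_errors=predicted,
        n_intrusions_observed=n_intrusions_observed,
        n_reps=n_reps,
        n_degenerate_reps=n_degenerate,
        seed=seed,
        all_degenerate=all_degenerate,
        ratio_saturated=saturated,
    )
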