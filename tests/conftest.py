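import numpy as np
import pytest

from sourceguess.coding import GenerationEvent, RecallEvent
from sourceguess.guessing import FrequencyNorms


@pytest.fixture
def toy_norms() -> FrequencyNorms:
    """One shape, three actions with probabilities 0.5 / 0.25 / 0.25."""
    return FrequencyNorms({"X": {"a": 0.5, "b": 0.25, "c": 0.25}})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_generation(pair="pair0", specs=()):
    """specs: iterable of (participant, shape, code, trial, role)."""
    return [
        GenerationEvent(
            pair_id=pair, participant_id=p, shape_id=s, action_code=c,
            trial_index=t, role=r,
        )
        for (p, s, c, t, r) in specs
    ]


def make_recall(participant, task, items, attributed=None):
    """items: iterable of (shape, code); attributed: optional flags."""
    flags = attributed or [True] * len(items)
    return [
        RecallEvent(
            participant_id=participant, task=task, shape_id=s, action_code=c,
            output_order=i + 1, attributed_to_target=f,
        )
        for i, ((s, c), f) in enumerate(zip(items, flags))
    ]
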