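"""Lightweight trial containers shared by the simulator and the models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .task_math import Condition

#: symbol coding: dog = 'D' (+1), cat = 'C' (-1)
SYMBOLS = {"D": 1, "C": -1, "dog": 1, "cat": -1}


def encode_stimuli(stimuli) -> np.ndarray:
    """Map a stimulus sequence ('D'/'C' string, symbol list, or +-1) to signs."""
    if isinstance(stimuli, str):
        try:
            return np.array([SYMBOLS[s] for s in stimuli], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"unknown stimulus symbol {exc.args[0]!r}") from None
    arr = list(stimuli)
    if arr and isinstance(arr[0], str):
        return np.array([SYMBOLS[s] for s in arr], dtype=np.int8)
    out = np.asarray(arr, dtype=np.int8)
    if not np.all(np.isin(out, (1, -1))):
        raise ValueError("stimulus signs must be +1 (dog) or -1 (cat)")
    return out


def decode_stimuli(signs: np.ndarray) -> str:
    return "".join("D" if s > 0 else "C" for s in signs)


class PrevSummary(NamedTuple):
    """What the previous trial contributes to the current decision.

    ``last_correct`` is coded +1 (correct) / -1 (incorrect) / 0 (no
    previous trial).
    """

    last_draw: int = 0
    last_correct: int = 0


@dataclass
class Trial:
    """A single sampling episode."""

    condition: Condition
    true_island: str  # 'left' or 'right'
    stimuli: str  # 20 chars over {D, C}
    n_samples: int
    choice: str
    correct: bool
    credits: float

    def __post_init__(self) -> None:
        if len(self.stimuli) != 20:
            raise ValueError("stimulus sequence must have length 20")
        if not 0 <= self.n_samples <= self.condition.max_samples:
            raise ValueError("n_samples outside [0, 20]")

    @property
    def signs(self) -> np.ndarray:
        return encode_stimuli(self.stimuli)
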