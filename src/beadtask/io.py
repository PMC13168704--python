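"""Readers/writers for the canonical trial table, plus run manifests.

The canonical on-disk form is a plain CSV with one row per trial:
participant_id, group, block_index, cost_level, evidence_level,
trial_index, n_samples, stimuli (20 characters over {D, C}), choice,
correct (0/1), credits.  ``column_map`` adapts externally deposited
data with different column names.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .task_math import COST_LEVELS, EVIDENCE_LEVELS

REQUIRED_COLUMNS = (
    "participant_id",
    "group",
    "block_index",
    "cost_level",
    "evidence_level",
    "trial_index",
    "n_samples",
    "stimuli",
    "choice",
    "correct",
    "credits",
)


def validate_trials(df: pd.DataFrame, allow_missing_stimuli: bool = False) -> list[str]:
    """Row-level invariant violations (empty list = valid)."""
    problems: list[str] = []
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    for idx, row in df.iterrows():
        n = row["n_samples"]
        if not 0 <= n <= 20:
            problems.append(f"row {idx}: n_samples={n} outside [0, 20]")
            continue
        if row["cost_level"] not in COST_LEVELS:
            problems.append(f"row {idx}: unknown cost_level {row['cost_level']!r}")
            continue
        if row["evidence_level"] not in EVIDENCE_LEVELS:
            problems.append(f"row {idx}: unknown evidence_level {row['evidence_level']!r}")
            continue
        stim = str(row["stimuli"])
        if len(stim) != 20 and not allow_missing_stimuli:
            problems.append(f"row {idx}: stimulus string has length {len(stim)}, expected 20")
        elif len(stim) < n:
            problems.append(f"row {idx}: stimulus string shorter than n_samples")
        if set(stim) - {"D", "C"}:
            problems.append(f"row {idx}: stimulus symbols outside {{D, C}}")
        c = COST_LEVELS[row["cost_level"]]
        expected = 100.0 * bool(row["correct"]) - c * n
        if abs(float(row["credits"]) - expected) > 1e-6:
            problems.append(
                f"row {idx}: credits {row['credits']} inconsistent with correct/cost (expected {expected})"
            )
    return problems


def read_trials(
    path,
    column_map: dict | None = None,
    allow_missing_stimuli: bool = False,
) -> pd.DataFrame:
    """Read and validate a trial CSV.

    ``column_map`` maps on-disk column names to canonical ones.  The
    returned frame carries ``attrs['short_form_ids']`` listing children
    with fewer than 96 trials (the short-form protocol).
    """
    df = pd.read_csv(path, dtype={"stimuli": str, "participant_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    problems = validate_trials(df, allow_missing_stimuli)
    if problems:
        head = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        raise ValueError(f"invalid trial table {path}:\n  {head}{more}")
    counts = df.groupby("participant_id").size()
    df.attrs["short_form_ids"] = sorted(counts.index[counts < 96])
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=[c for c in REQUIRED_COLUMNS if c in df.columns])


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline artifact."""

    command: str
    seeds: dict
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""
    software: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.software:
            import numpy
            import pandas
            import scipy

            from . import __version__

            self.software = {
                "beadtask": __version__,
                "python": platform.python_version(),
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            }

    def add_file(self, role: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        (self.inputs if role == "input" else self.outputs)[str(path)] = digest

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
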