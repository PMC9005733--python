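"""Task design, trial filtering/censoring, efficiency scoring and blinding.

The behavioural task is a two-alternative motion discrimination: children
judge whether dots move left or right, in either a motion-coherence task
(difficulty = % coherently moving dots) or a direction-integration task
(difficulty = angular SD of dot directions). Each task has 4 experimental
blocks of 38 trials: 9 repetitions x 2 difficulty levels x 2 directions
plus 2 full-strength catch trials, with a 2500 ms response deadline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialDesign",
    "build_design",
    "filter_trials",
    "efficiency_score",
    "blind_labels",
    "unblind_labels",
    "TRIAL_COLUMNS",
]

#: Column dictionary for trial tables (the tidy per-trial record).
TRIAL_COLUMNS = {
    "participant": "participant identifier",
    "group": "group label ('autistic' or 'comparison')",
    "task": "'motion_coherence' or 'direction_integration'",
    "block": "experimental block index (0-based)",
    "difficulty": "'easy', 'difficult' or 'catch'",
    "direction": "true stimulus direction, 'left' or 'right'",
    "response": "'left', 'right' or 'none'",
    "rt": "response time in seconds (NaN when no response)",
    "censored": "True when no response was made by the deadline",
    "excluded": "True when the trial is excluded from model fitting",
    "exclusion_reason": "why the trial was excluded ('' if retained)",
}

_DIFFICULTY_DEFAULTS = {
    # value of the difficulty manipulation at the difficult and easy level
    "motion_coherence": {"difficult": 30.0, "easy": 75.0, "catch": 100.0, "unit": "% coherence"},
    "direction_integration": {"difficult": 70.0, "easy": 30.0, "catch": 0.0, "unit": "deg SD"},
}


@dataclass(frozen=True)
class TrialDesign:
    """Fully specified block structure for one task."""

    task: str
    blocks: int = 4
    repetitions: int = 9          # per (difficulty x direction) cell per block
    catch_per_block: int = 2
    difficulty_values: dict = field(default_factory=dict)
    deadline: float = 2.5         # s
    rt_floor: float = 0.2         # s

    @property
    def trials_per_block(self) -> int:
        return self.repetitions * 2 * 2 + self.catch_per_block

    @property
    def total_trials(self) -> int:
        return self.trials_per_block * self.blocks

    def schedule(self, seed: int | None = None) -> pd.DataFrame:
        """Enumerate and (seeded) shuffle the trial schedule.

        Shuffling is uniform within block. Catch trials alternate direction.
        """
        rng = np.random.default_rng(seed)
        rows = []
        for b in range(self.blocks):
            block_rows = []
            for diff in ("easy", "difficult"):
                for direction in ("left", "right"):
                    block_rows += [(b, diff, direction)] * self.repetitions
            for c in range(self.catch_per_block):
                block_rows.append((b, "catch", "left" if c % 2 == 0 else "right"))
            order = rng.permutation(len(block_rows))
            rows += [block_rows[i] for i in order]
        df = pd.DataFrame(rows, columns=["block", "difficulty", "direction"])
        df.insert(0, "task", self.task)
        df["trial"] = np.arange(len(df))
        return df


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the documented columns (see
    :data:`TRIAL_COLUMNS`); extra columns are preserved."""
    table.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV, checking the core column dictionary."""
    df = pd.read_csv(path)
    core = {"participant", "group", "task", "difficulty", "direction",
            "response", "rt"}
    missing = core - set(df.columns)
    if missing:
        raise ValueError(f"trial table at {path} missing columns {sorted(missing)}")
    return df


def build_design(task: str, **overrides) -> TrialDesign:
    """Construct the task design, defaulting to the standard protocol
    (4 blocks x 38 trials; coherence 30%/75% or direction SD 70/30 deg)."""
    if task not in _DIFFICULTY_DEFAULTS:
        raise ValueError(
            f"unknown task {task!r}; expected 'motion_coherence' or 'direction_integration'"
        )
    for key in ("blocks", "repetitions", "catch_per_block"):
        if key in overrides and overrides[key] < 0:
            raise ValueError(f"{key} must be >= 0, got {overrides[key]}")
    values = dict(_DIFFICULTY_DEFAULTS[task])
    values.update(overrides.pop("difficulty_values", {}))
    return TrialDesign(task=task, difficulty_values=values, **overrides)


def filter_trials(table: pd.DataFrame, rt_floor: float = 0.2,
                  deadline: float = 2.5):
    """Mark fast-guess trials excluded and no-response trials censored.

    Trials with RT below ``rt_floor`` (200 ms by default) are marked
    excluded (never deleted); trials without a response are marked censored
    and retained for the likelihood as non-terminating accumulation
    trajectories. Returns ``(table, report)`` where ``report`` gives the
    per-group excluded and censored percentages.
    """
    if rt_floor >= deadline:
        raise ValueError(f"rt_floor ({rt_floor}) must be below the deadline ({deadline})")
    responded = table["response"] != "none"
    rt = table["rt"].to_numpy(dtype=float)
    if np.any(rt[responded.to_numpy()] < 0):
        raise ValueError("corrupt input: negative RT on a responded trial")

    out = table.copy()
    out["censored"] = ~responded
    excluded = responded & (out["rt"] < rt_floor)
    out["excluded"] = excluded
    out["exclusion_reason"] = np.where(excluded, "rt_floor", "")

    grp = out.groupby("group", observed=True)
    report = pd.DataFrame({
        "pct_excluded": grp["excluded"].mean() * 100.0,
        "pct_censored": grp["censored"].mean() * 100.0,
        "n_trials": grp.size(),
    })
    return out, report


def efficiency_score(block: pd.DataFrame, median_over: str = "correct",
                     floor: int = 10) -> int:
    """Points awarded for one block: round((1 / median RT) * n_correct * 2),
    floored at 10 so that children are never demotivated by a low score.

    ``median_over`` selects which responded trials define the median RT:
    ``"correct"`` (default) or ``"all"``.
    """
    if len(block) == 0:
        raise ValueError("efficiency score of an empty block is undefined")
    responded = block[block["response"] != "none"]
    correct = responded[responded["response"] == responded["direction"]]
    if len(correct) == 0:
        return floor
    basis = correct if median_over == "correct" else responded
    if median_over not in ("correct", "all"):
        raise ValueError(f"median_over must be 'correct' or 'all', got {median_over!r}")
    med = float(basis["rt"].median())
    raw = int(round((1.0 / med) * len(correct) * 2.0))
    return max(raw, floor)


def blind_labels(table: pd.DataFrame, seed: int):
    """Randomly permute group labels at the participant level.

    Returns ``(blinded_table, key)``; ``key`` maps each participant to its
    true group and is meant to be stored separately by the (unblinded)
    analyst. Group sizes are preserved because labels are permuted, not
    resampled.
    """
    participants = table["participant"].drop_duplicates().to_numpy()
    if len(participants) < 2:
        raise ValueError("blinding requires at least 2 participants")
    true = (table.drop_duplicates("participant").set_index("participant")["group"])
    rng = np.random.default_rng(seed)
    permuted = true.to_numpy()[rng.permutation(len(participants))]
    mapping = pd.Series(permuted, index=true.index, name="group")
    out = table.copy()
    out["group"] = out["participant"].map(mapping)
    key = pd.DataFrame({"participant": true.index, "group": true.to_numpy()})
    return out, key


def unblind_labels(table: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Restore true group labels from the blinding key."""
    mapping = key.set_index("participant")["group"]
    out = table.copy()
    out["group"] = out["participant"].map(mapping)
    return out
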