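"""Behavioral outcome scores: corner test, neurodeficit score, and the
nine-item day-30 neuroscore battery.

Corner test.  Over 10 trials in a 30-degree walled corner, the index is
``abs((L - R) / (L + R))`` for left/right turn counts — 0 for perfectly
symmetric turning, 1 for fully lateralized turning.  With no completed
turns the index is undefined and reported as missing, never as 0.

Neurodeficit score (modified Bederson).  Four observed deficit
categories — asymmetric forelimb/torso turning, circling, inability to
bear weight, absence of movement.  The default scoring awards one point
per observed category (0-4), matching the graded score evolution seen
over follow-up; a strict binary reading (any deficit = 1) is available
via ``mode="binary"``.

Neuroscore battery.  Nine items each rated 0 (normal) to 3 (most
impaired): spontaneous activity, circling, limb symmetry, forepaw
outstretch, body/trunk sensation, vibrissae sensation, face sensation,
beam walk and grid climb (the timed tests enter as pre-scored 0-3
items).  The composite is the plain sum, 0-27.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NDS_DEFICITS",
    "BATTERY_ITEMS",
    "CornerTrialRecord",
    "NDSObservation",
    "NeuroscoreBattery",
    "corner_index",
    "nds_score",
    "battery_composite",
    "read_corner_csv",
    "read_nds_csv",
    "read_battery_csv",
    "score_corner_table",
    "score_nds_table",
    "score_battery_table",
]

NDS_DEFICITS = (
    "asymmetric_forelimb_torso_turning",
    "circling",
    "inability_bear_weight",
    "absence_of_movement",
)

BATTERY_ITEMS = (
    "spontaneous_activity",
    "circling",
    "limb_symmetry",
    "forepaw_outstretch",
    "body_trunk_sensation",
    "vibrissae_sensation",
    "face_sensation",
    "beam_walk",
    "grid_climb",
)

MAX_CORNER_TRIALS = 10


@dataclass
class CornerTrialRecord:
    subject_id: str
    day: int                      # -7 baseline, 7, 30
    left_turns: int
    right_turns: int

    def __post_init__(self) -> None:
        if self.left_turns < 0 or self.right_turns < 0:
            raise ValueError("turn counts must be non-negative")
        if self.left_turns + self.right_turns > MAX_CORNER_TRIALS:
            raise ValueError(
                f"{self.left_turns}+{self.right_turns} turns exceed "
                f"{MAX_CORNER_TRIALS} trials")

    @property
    def index(self) -> float | None:
        return corner_index(self.left_turns, self.right_turns)


@dataclass
class NDSObservation:
    subject_id: str
    day: int                      # 1, 2 or 30
    deficits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.deficits = frozenset(self.deficits)
        unknown = self.deficits - set(NDS_DEFICITS)
        if unknown:
            raise ValueError(f"unknown deficit categories: {sorted(unknown)}")

    def score(self, mode: str = "per_category") -> int:
        return nds_score(self.deficits, mode=mode)


@dataclass
class NeuroscoreBattery:
    subject_id: str
    items: dict[str, int]
    day: int = 30

    def __post_init__(self) -> None:
        unknown = set(self.items) - set(BATTERY_ITEMS)
        if unknown:
            raise ValueError(f"unknown battery items: {sorted(unknown)}")
        for name, v in self.items.items():
            if not 0 <= int(v) <= 3:
                raise ValueError(f"item {name}={v} outside 0-3")

    def composite(self) -> int:
        return battery_composite(self.items)


def corner_index(left_turns: int, right_turns: int) -> float | None:
    """abs((L - R) / (L + R)); None (undefined) when no turn was made."""
    if left_turns < 0 or right_turns < 0:
        raise ValueError("turn counts must be non-negative")
    total = left_turns + right_turns
    if total == 0:
        return None
    return abs(left_turns - right_turns) / total


def nds_score(deficits, mode: str = "per_category") -> int:
    """Neurodeficit score from the observed deficit set.

    ``per_category`` (default): one point per category, 0-4.
    ``binary``: 0 if normal, 1 if any deficit.
    """
    deficits = frozenset(deficits)
    unknown = deficits - set(NDS_DEFICITS)
    if unknown:
        raise ValueError(f"unknown deficit categories: {sorted(unknown)}")
    if mode == "per_category":
        return len(deficits)
    if mode == "binary":
        return int(bool(deficits))
    raise ValueError(f"unknown nds_mode {mode!r}")


class MissingItemError(ValueError):
    """A battery item is absent; the composite is undefined, not zero."""


def battery_composite(items: dict[str, int]) -> int:
    """Sum of the nine 0-3 battery items (0-27); all items must be present."""
    missing = [k for k in BATTERY_ITEMS if k not in items or pd.isna(items[k])]
    if missing:
        raise MissingItemError(f"missing battery items: {missing}")
    vals = {k: int(items[k]) for k in BATTERY_ITEMS}
    bad = {k: v for k, v in vals.items() if not 0 <= v <= 3}
    if bad:
        raise ValueError(f"battery items outside 0-3: {bad}")
    return sum(vals.values())


# -- CSV interface ------------------------------------------------------------
# Column names are fixed: corner tables need subject_id, day, left_turns,
# right_turns; NDS tables need subject_id, day plus one 0/1 column per
# deficit category; battery tables need subject_id plus one 0-3 column
# per item (optionally day).


def read_corner_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    needed = {"subject_id", "day", "left_turns", "right_turns"}
    if not needed <= set(df.columns):
        raise ValueError(f"corner CSV must have columns {sorted(needed)}")
    return df


def score_corner_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``corner_index`` column; undefined indices become NaN with
    ``undefined=True``."""
    out = df.copy()
    idx, undef = [], []
    for _, row in out.iterrows():
        rec = CornerTrialRecord(str(row["subject_id"]), int(row["day"]),
                                int(row["left_turns"]), int(row["right_turns"]))
        v = rec.index
        idx.append(np.nan if v is None else v)
        undef.append(v is None)
    out["corner_index"] = idx
    out["undefined"] = undef
    return out


def read_nds_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    needed = {"subject_id", "day", *NDS_DEFICITS}
    if not needed <= set(df.columns):
        raise ValueError(f"NDS CSV must have columns {sorted(needed)}")
    return df


def score_nds_table(df: pd.DataFrame, mode: str = "per_category") -> pd.DataFrame:
    out = df.copy()
    scores = []
    for _, row in out.iterrows():
        deficits = frozenset(d for d in NDS_DEFICITS if int(row[d]) == 1)
        scores.append(nds_score(deficits, mode=mode))
    out["nds_score"] = scores
    return out


def read_battery_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    needed = {"subject_id", *BATTERY_ITEMS}
    if not needed <= set(df.columns):
        raise ValueError(f"battery CSV must have columns {sorted(needed)}")
    return df


def score_battery_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``composite`` column; rows with missing items get NaN and
    ``missing_items=True``."""
    out = df.copy()
    comp, missing = [], []
    for _, row in out.iterrows():
        try:
            comp.append(battery_composite({k: row[k] for k in BATTERY_ITEMS
                                           if k in row and pd.notna(row[k])}))
            missing.append(False)
        except MissingItemError:
            comp.append(np.nan)
            missing.append(True)
    out["composite"] = comp
    out["missing_items"] = missing
    return out
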