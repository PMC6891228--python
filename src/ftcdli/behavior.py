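"""Handedness quotients and behavioural-annotation arithmetic.

Hand preference is summarised by the laterality quotient
LQ = (R - L) / (R + L + Both) * 100, from counts of right-hand,
left-hand and bimanual responses.  Video annotations exported as
tab-delimited tables (tier, onset, offset, trial, period) yield a
hand-movement dominance index, a per-trial communication duration
(overlapping annotations merged so communication of any type is counted
once), and flags for trials where the child communicated during the
baseline or rest period — those flags feed the preprocessing pipeline's
behavioural rejects.  Very brief annotations (default < 0.5 s: grooming,
brief points, single short vocalisations) are ignored before any
aggregation; the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HandednessCounts",
    "laterality_quotient",
    "read_annotations",
    "hand_dominance_index",
    "communication_per_trial",
    "merge_intervals",
]

TIERS = ("right-hand", "left-hand", "speech")
PERIODS = ("baseline", "active", "rest")
DEFAULT_MIN_DURATION = 0.5


@dataclass(frozen=True)
class HandednessCounts:
    """Trial counts of a hand-preference task (card reaching or object use)."""

    right: int
    left: int
    both: int
    task: str = "card"

    def __post_init__(self) -> None:
        if min(self.right, self.left, self.both) < 0:
            raise ValueError("counts must be non-negative")
        if self.right + self.left + self.both == 0:
            raise ValueError("total count must be > 0")


def laterality_quotient(counts: HandednessCounts) -> float:
    """LQ = (R - L) / (R + L + Both) * 100, in [-100, 100]."""
    total = counts.right + counts.left + counts.both
    return 100.0 * (counts.right - counts.left) / total


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited annotation export (tier, onset, offset, trial, period)."""
    df = pd.read_csv(path, sep="\t")
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    required = {"tier", "onset", "offset", "trial", "period"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table is missing columns: {sorted(missing)}")
    if (df["offset"] <= df["onset"]).any():
        bad = df.index[df["offset"] <= df["onset"]].tolist()
        raise ValueError(f"offset must exceed onset (rows {bad})")
    unknown_tier = set(df["tier"]) - set(TIERS)
    if unknown_tier:
        raise ValueError(f"unknown tiers: {sorted(unknown_tier)}")
    unknown_period = set(df["period"]) - set(PERIODS)
    if unknown_period:
        raise ValueError(f"unknown periods: {sorted(unknown_period)}")
    return df


def _filtered(df: pd.DataFrame, min_duration: float) -> pd.DataFrame:
    dur = df["offset"] - df["onset"]
    return df[dur >= min_duration]


def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list:
    """Union of half-open intervals; idempotent and order-invariant."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged: list = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def hand_dominance_index(
    df: pd.DataFrame, min_duration: float = DEFAULT_MIN_DURATION
) -> float:
    """(R - L) / (R + L) * 100 over active-period hand-movement seconds.

    Each tier's seconds are counted as annotated, so bimanual time
    contributes to both tiers.
    """
    d = _filtered(validate_annotations(df), min_duration)
    active = d[d["period"] == "active"]
    r = float((active.loc[active["tier"] == "right-hand", "offset"]
               - active.loc[active["tier"] == "right-hand", "onset"]).sum())
    l = float((active.loc[active["tier"] == "left-hand", "offset"]
               - active.loc[active["tier"] == "left-hand", "onset"]).sum())
    if r + l == 0:
        raise ValueError("no hand movement annotated in active periods")
    return 100.0 * (r - l) / (r + l)


def communication_per_trial(
    df: pd.DataFrame,
    n_viable_trials: int,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> tuple[float, list]:
    """Mean seconds of communication (any tier) per active period, plus flags.

    Overlapping annotations within a trial's active period are merged
    across tiers before summing, so simultaneous speech and sign are
    counted once.  The second return value lists trials with any
    annotation in the baseline or rest period — candidates for
    behavioural rejection in the signal pipeline.
    """
    if n_viable_trials < 1:
        raise ValueError("n_viable_trials must be >= 1")
    d = _filtered(validate_annotations(df), min_duration)
    active = d[d["period"] == "active"]
    total = 0.0
    for _trial, grp in active.groupby("trial"):
        for a, b in merge_intervals(zip(grp["onset"], grp["offset"])):
            total += b - a
    flagged = sorted(
        int(t) for t in d.loc[d["period"].isin(("baseline", "rest")), "trial"].unique()
    )
    return total / n_viable_trials, flagged
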