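"""Longitudinal stability of profile membership.

Each participant in the follow-up subsample is allocated to a profile at
every monthly timepoint (by default with the fixed 3-variable allocation
tree). The stability score is the fraction of timepoints spent in the
participant's most frequent (modal) profile: for 6 timepoints and 4 profiles
it ranges from 1/3 (migrating across all four profiles) to 1 (never changed).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from copd_profiles.tree import TreeModel, predict

logger = logging.getLogger(__name__)

MOVEMENT_CATEGORIES = ("fully-stable", "two-profile", "three-or-more")


def stability_score(labels: Sequence[int]) -> float:
    """Modal-profile timepoint count divided by the number of timepoints."""
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("empty trajectory")
    if len(labels) < 2:
        raise ValueError("a trajectory needs at least 2 timepoints")
    return max(Counter(labels).values()) / len(labels)


def modal_profile(labels: Sequence[int]) -> int:
    """Most frequent profile; ties go to the profile that reaches the modal
    count earliest in the trajectory."""
    labels = list(labels)
    counts = Counter(labels)
    modal_count = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == modal_count}
    running: Counter = Counter()
    for lab in labels:
        running[lab] += 1
        if lab in tied and running[lab] == modal_count:
            return int(lab)
    raise AssertionError("unreachable")


def movement_category(labels: Sequence[int]) -> str:
    """fully-stable (one distinct profile), two-profile, or three-or-more."""
    distinct = len(set(labels))
    if distinct == 1:
        return "fully-stable"
    if distinct == 2:
        return "two-profile"
    return "three-or-more"


@dataclass(frozen=True)
class ProfileTrajectory:
    """One participant's follow-up classification history."""

    participant_id: int
    labels: tuple[int, ...]
    modal: int
    modal_count: int
    score: float
    distinct_profiles: int
    category: str
    #: True when the modal profile covers at least half the follow-up
    #: (>= 3 of 6 months): the participant stayed 'predominantly' in it.
    predominant: bool


def _make_trajectory(participant_id: int, labels: Sequence[int]) -> ProfileTrajectory:
    labels = tuple(int(v) for v in labels)
    modal = modal_profile(labels)
    modal_count = labels.count(modal)
    return ProfileTrajectory(
        participant_id=int(participant_id),
        labels=labels,
        modal=modal,
        modal_count=modal_count,
        score=stability_score(labels),
        distinct_profiles=len(set(labels)),
        category=movement_category(labels),
        predominant=modal_count >= int(np.ceil(len(labels) / 2)),
    )


def assign_over_time(
    classifier: TreeModel,
    longitudinal: pd.DataFrame,
    timepoints: Sequence[int] | None = None,
    fev1_source: str = "baseline",
) -> tuple[list[ProfileTrajectory], list[int]]:
    """Classify every follow-up record and build per-participant trajectories.

    ``timepoints`` defaults to the follow-up months present in the table
    (baseline, timepoint 0, is excluded from the score). Participants missing
    any required timepoint are excluded and logged, mirroring a complete-case
    follow-up analysis. Spirometry is typically a baseline-only assessment in
    monthly follow-up protocols, so by default each participant's timepoint-0
    FEV1 is substituted for the follow-up values (``fev1_source='baseline'``);
    pass ``'record'`` to use re-measured FEV1 where it exists.

    Returns (trajectories, excluded participant ids).
    """
    if longitudinal.empty:
        raise ValueError("empty longitudinal cohort")
    follow = longitudinal[longitudinal["timepoint"] > 0].copy()
    if timepoints is None:
        timepoints = sorted(follow["timepoint"].unique())
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("no follow-up timepoints in input")

    if fev1_source == "baseline":
        base = longitudinal[longitudinal["timepoint"] == 0].set_index("participant_id")["fev1_pct"]
        if not base.empty:
            mapped = follow["participant_id"].map(base)
            follow.loc[mapped.notna(), "fev1_pct"] = mapped[mapped.notna()]
    elif fev1_source != "record":
        raise ValueError("fev1_source must be 'record' or 'baseline'")

    trajectories: list[ProfileTrajectory] = []
    excluded: list[int] = []
    for pid, group in follow.groupby("participant_id", sort=True):
        group = group.set_index("timepoint")
        if not all(t in group.index for t in timepoints):
            missing = [t for t in timepoints if t not in group.index]
            logger.info("participant %s excluded: missing timepoints %s", pid, missing)
            excluded.append(int(pid))
            continue
        ordered = group.loc[timepoints].reset_index()
        labels = predict(classifier, ordered)
        trajectories.append(_make_trajectory(pid, labels))
    if not trajectories:
        raise ValueError("no participant has complete follow-up data")
    return trajectories, excluded


@dataclass(frozen=True)
class StabilitySummary:
    """Cohort-level stability figures plus a textual flow summary."""

    n_participants: int
    proportion_fully_stable: float
    proportion_two_profile: float
    proportion_three_or_more: float
    mean_stability_pct: float
    sd_stability_pct: float
    per_profile_mean_score: dict[int, float]
    baseline_profile_counts: dict[int, int]
    #: counts of month-to-month moves between ordered profile pairs
    flows: dict[tuple[int, int], int]

    def flow_text(self) -> str:
        lines = [f"Participants followed: {self.n_participants}"]
        lines.append("Baseline profile counts: " + ", ".join(
            f"profile {p}: {n}" for p, n in sorted(self.baseline_profile_counts.items())
        ))
        moves = {k: v for k, v in sorted(self.flows.items()) if k[0] != k[1] and v > 0}
        if not moves:
            lines.append("No movement between profiles.")
        else:
            lines.append("Movements between profiles (from -> to: count):")
            lines.extend(f"  {a} -> {b}: {n}" for (a, b), n in moves.items())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "proportion_fully_stable": self.proportion_fully_stable,
            "proportion_two_profile": self.proportion_two_profile,
            "proportion_three_or_more": self.proportion_three_or_more,
            "mean_stability_pct": self.mean_stability_pct,
            "sd_stability_pct": self.sd_stability_pct,
            "per_profile_mean_score": {str(k): v for k, v in self.per_profile_mean_score.items()},
            "baseline_profile_counts": {str(k): v for k, v in self.baseline_profile_counts.items()},
            "flows": {f"{a}->{b}": n for (a, b), n in sorted(self.flows.items())},
            "flow_summary": self.flow_text(),
        }


def cohort_stability_summary(trajectories: Sequence[ProfileTrajectory]) -> StabilitySummary:
    """Aggregate per-participant trajectories into the cohort summary."""
    if len(trajectories) == 0:
        raise ValueError("no trajectories")
    n = len(trajectories)
    categories = Counter(t.category for t in trajectories)
    scores = np.array([t.score for t in trajectories])
    per_profile: dict[int, list[float]] = {}
    baseline_counts: Counter = Counter()
    flows: Counter = Counter()
    for t in trajectories:
        per_profile.setdefault(t.modal, []).append(t.score)
        baseline_counts[t.labels[0]] += 1
        for a, b in zip(t.labels[:-1], t.labels[1:]):
            if a != b:
                flows[(a, b)] += 1
    return StabilitySummary(
        n_participants=n,
        proportion_fully_stable=categories.get("fully-stable", 0) / n,
        proportion_two_profile=categories.get("two-profile", 0) / n,
        proportion_three_or_more=categories.get("three-or-more", 0) / n,
        mean_stability_pct=float(100.0 * scores.mean()),
        sd_stability_pct=float(100.0 * scores.std(ddof=1)) if n > 1 else 0.0,
        per_profile_mean_score={p: float(np.mean(v)) for p, v in sorted(per_profile.items())},
        baseline_profile_counts={p: int(c) for p, c in sorted(baseline_counts.items())},
        flows=dict(flows),
    )


def trajectories_frame(trajectories: Sequence[ProfileTrajectory]) -> pd.DataFrame:
    """Per-participant trajectory table for delimited-text output."""
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trajectories],
            "labels": ["-".join(map(str, t.labels)) for t in trajectories],
            "modal_profile": [t.modal for t in trajectories],
            "modal_count": [t.modal_count for t in trajectories],
            "stability_score": [t.score for t in trajectories],
            "distinct_profiles": [t.distinct_profiles for t in trajectories],
            "movement_category": [t.category for t in trajectories],
            "predominant": [t.predominant for t in trajectories],
        }
    )
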