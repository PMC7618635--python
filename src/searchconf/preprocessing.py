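"""Fixation, trial and participant screening, and the minimum gaze-target
distance.

Screening rules, applied in order:

1. Fixations shorter than 150 ms are discarded (too short to take up
   information).
2. A trial is invalid when either of its two search intervals has no retained
   fixation on the search stimulus (within the disc of radius
   ``7.5 * scale`` degrees) or contains a blink.
3. A participant is excluded when more than 10% of their main trials are
   invalid (strict inequality; practice trials never count).

The central statistic is ``dmin``, the minimum Euclidean distance between the
target location and the mean position of any retained fixation of the
interval, computed only for valid target-present intervals.  All coordinates
are degrees of visual angle with the origin at the stimulus centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MIN_FIXATION_DURATION_MS",
    "PARTICIPANT_INVALID_MAX",
    "ValidityReport",
    "filter_fixations",
    "flag_trials",
    "min_gaze_target_distance",
    "compute_distances",
    "preprocess",
]

MIN_FIXATION_DURATION_MS = 150.0
PARTICIPANT_INVALID_MAX = 0.10


@dataclass
class ValidityReport:
    """Outcome of trial/participant screening.

    trial_validity : per (participant, trial) row: valid flag and reason
        (``ok``, ``no_fixation`` or ``blink``).
    participant_summary : per participant: number of main trials, invalid
        fraction and the exclusion flag (invalid fraction strictly above 10%).
    fixation_removed_fraction : fraction of fixations dropped by the duration
        filter, ``None`` when there were no fixations at all.
    """

    trial_validity: pd.DataFrame
    participant_summary: pd.DataFrame
    fixation_removed_fraction: float | None

    @property
    def excluded_participants(self) -> list:
        s = self.participant_summary
        return list(s.loc[s["excluded"], "participant"])


def filter_fixations(fixations: pd.DataFrame,
                     min_duration_ms: float = MIN_FIXATION_DURATION_MS,
                     ) -> tuple[pd.DataFrame, float | None]:
    """Drop fixations shorter than ``min_duration_ms``.

    The boundary stays: a fixation of exactly 150 ms is retained ("less than
    150 ms" are excluded).  Returns the retained rows and the removed
    fraction (``None`` for empty input, which is distinct from 0.0).
    """
    if (fixations["duration_ms"] <= 0).any():
        raise ValueError("fixation durations must be positive")
    if len(fixations) == 0:
        return fixations.copy(), None
    keep = fixations["duration_ms"] >= min_duration_ms
    return fixations.loc[keep].copy(), float(1.0 - keep.mean())


def flag_trials(trials: pd.DataFrame, fixations: pd.DataFrame,
                radius_factor: float = 7.5,
                max_invalid_fraction: float = PARTICIPANT_INVALID_MAX,
                ) -> ValidityReport:
    """Screen trials and participants.

    ``fixations`` must already be duration-filtered.  An interval counts as
    covered when at least one retained fixation lies within the stimulus disc
    of radius ``radius_factor * scale``.  Blink flags are read from the
    ``blink`` column of ``trials`` (per interval).  Practice trials are
    screened too but do not count towards participant exclusion.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    removed_fraction = None  # caller may supply via preprocess()

    fx = fixations.merge(
        trials[["participant", "trial", "interval", "scale"]],
        on=["participant", "trial", "interval"], how="left")
    r = np.hypot(fx["x_deg"], fx["y_deg"])
    fx_on = fx.loc[r <= radius_factor * fx["scale"] + 1e-12]
    covered = set(map(tuple, fx_on[["participant", "trial", "interval"]]
                      .drop_duplicates().to_numpy()))

    records = []
    for (p, t), grp in trials.groupby(["participant", "trial"], sort=True):
        no_fix = any((p, t, iv) not in covered for iv in grp["interval"])
        blink = bool(grp["blink"].any())
        if no_fix:
            reason = "no_fixation"
        elif blink:
            reason = "blink"
        else:
            reason = "ok"
        records.append((p, t, bool(grp["practice"].iloc[0]),
                        reason == "ok", reason))
    trial_validity = pd.DataFrame(
        records, columns=["participant", "trial", "practice", "valid", "reason"])

    main = trial_validity.loc[~trial_validity["practice"]]
    summary = []
    for p, grp in main.groupby("participant", sort=True):
        if len(grp) == 0:
            raise ValueError(f"participant {p!r} has no main trials")
        frac = float(1.0 - grp["valid"].mean())
        summary.append((p, len(grp), frac, frac > max_invalid_fraction))
    participant_summary = pd.DataFrame(
        summary,
        columns=["participant", "n_main_trials", "invalid_fraction", "excluded"])
    return ValidityReport(trial_validity, participant_summary, removed_fraction)


def min_gaze_target_distance(fixations: pd.DataFrame,
                             target_position: tuple[float, float]) -> float:
    """Minimum Euclidean distance from the target to any retained fixation."""
    if len(fixations) == 0:
        raise ValueError("no retained fixations: dmin undefined")
    dx = fixations["x_deg"].to_numpy() - target_position[0]
    dy = fixations["y_deg"].to_numpy() - target_position[1]
    return float(np.sqrt(dx * dx + dy * dy).min())


def compute_distances(trials: pd.DataFrame,
                      fixations: pd.DataFrame) -> pd.DataFrame:
    """dmin per valid target-present interval, on duration-filtered fixations.

    Intervals without any retained fixation are dropped (their trial is
    already invalid).  Returns columns participant, trial, interval, dmin,
    n_fixations_used.
    """
    present = trials.loc[trials["target_present"]]
    fx = fixations.merge(
        present[["participant", "trial", "interval",
                 "target_x_deg", "target_y_deg"]],
        on=["participant", "trial", "interval"], how="inner")
    if len(fx) == 0:
        return pd.DataFrame(columns=["participant", "trial", "interval",
                                     "dmin", "n_fixations_used"])
    fx = fx.assign(dist=np.hypot(fx["x_deg"] - fx["target_x_deg"],
                                 fx["y_deg"] - fx["target_y_deg"]))
    out = (fx.groupby(["participant", "trial", "interval"], sort=True)["dist"]
             .agg(dmin="min", n_fixations_used="size").reset_index())
    out["n_fixations_used"] = out["n_fixations_used"].astype(int)
    return out


def preprocess(trials: pd.DataFrame, fixations: pd.DataFrame,
               min_duration_ms: float = MIN_FIXATION_DURATION_MS,
               radius_factor: float = 7.5,
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, ValidityReport]:
    """Full screening pipeline.

    Returns ``(trials_clean, fixations_retained, distances, report)`` where
    ``trials_clean`` holds only valid main trials of retained participants.
    """
    fx, removed = filter_fixations(fixations, min_duration_ms)
    report = flag_trials(trials, fx, radius_factor)
    report.fixation_removed_fraction = removed

    valid = report.trial_validity
    keep_trials = valid.loc[valid["valid"] & ~valid["practice"],
                            ["participant", "trial"]]
    excluded = set(report.excluded_participants)
    keep_trials = keep_trials.loc[~keep_trials["participant"].isin(excluded)]
    trials_clean = trials.merge(keep_trials, on=["participant", "trial"])
    fx_clean = fx.merge(keep_trials, on=["participant", "trial"])
    distances = compute_distances(trials_clean, fx_clean)
    return trials_clean, fx_clean, distances, report
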