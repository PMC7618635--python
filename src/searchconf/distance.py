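"""ROC/AUC analyses of the minimum gaze-target distance and sliding-window
rate curves.

Detection of a small peripheral target works only when the gaze comes close
to it, so the distribution of ``dmin`` (minimum gaze-target distance of an
interval) should differ between detected and missed targets, and between
confidence-chosen and non-chosen intervals.  The comparison statistic is the
rank-based AUC: the probability that a randomly drawn negative-outcome
interval (miss, or non-chosen) has a *larger* distance than a positive one
(hit, or chosen), ties counted half.  AUC 0.5 means the distributions are
indistinguishable; values above 0.5 mean misses/non-chosen lie farther from
the target.

Rate-versus-distance curves use adjacent half-open bins of 0.5 degrees
(window size equals step size); bins with fewer than 6 observations are
reported as missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .regression import pearson

__all__ = [
    "rank_auc",
    "auc_by_participant",
    "sliding_window_rate",
    "window_curves_by_participant",
    "cross_participant_correlation",
    "curve_correlation",
]

DEFAULT_WINDOW = 0.5
DEFAULT_MIN_OBS = 6


def rank_auc(distances_positive, distances_negative) -> float:
    """Mann-Whitney AUC: P(negative distance > positive distance) + half-ties.

    ``distances_positive`` are the favourable outcomes (hits or chosen
    intervals), ``distances_negative`` the unfavourable ones (misses or
    non-chosen).  Equivalent to the area under the empirical ROC curve swept
    over all distance thresholds.
    """
    pos = np.asarray(distances_positive, dtype=float)
    neg = np.asarray(distances_negative, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    u = mannwhitneyu(neg, pos, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def auc_by_participant(distances: pd.DataFrame, positive_mask,
                       contrast_name: str) -> pd.DataFrame:
    """Per-participant rank AUC between the two outcome groups.

    ``distances`` needs columns participant and dmin; ``positive_mask`` is a
    boolean array aligned to its rows.  Participants lacking either group get
    NaN.
    """
    positive_mask = np.asarray(positive_mask, dtype=bool)
    rows = []
    for p, grp in distances.groupby("participant", sort=True):
        mask = positive_mask[distances.index.get_indexer(grp.index)]
        pos = grp.loc[mask, "dmin"].to_numpy()
        neg = grp.loc[~mask, "dmin"].to_numpy()
        rows.append((p, contrast_name, rank_auc(pos, neg), len(pos), len(neg)))
    return pd.DataFrame(rows, columns=["participant", "contrast", "auc",
                                       "n_positive", "n_negative"])


def sliding_window_rate(dmin, outcome, window: float = DEFAULT_WINDOW,
                        step: float = DEFAULT_WINDOW,
                        min_obs: int = DEFAULT_MIN_OBS,
                        max_distance: float | None = None) -> pd.DataFrame:
    """Binary-outcome rate in distance bins ``[k*step, k*step + window)``.

    With the default window == step the bins are adjacent and half-open,
    starting at 0.  Bins with fewer than ``min_obs`` observations have a NaN
    rate (but their count is still reported); trailing empty bins are
    suppressed.
    """
    d = np.asarray(dmin, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if len(d) == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "rate", "n_obs"])
    top = max_distance if max_distance is not None else float(d.max())
    n_bins = max(int(np.floor(top / step)) + 1, 1)
    rows = []
    for k in range(n_bins):
        lo = k * step
        hi = lo + window
        in_bin = (d >= lo) & (d < hi)
        n = int(in_bin.sum())
        rate = float(y[in_bin].mean()) if n >= min_obs else float("nan")
        rows.append((lo, hi, rate, n))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "rate", "n_obs"])


def window_curves_by_participant(records: pd.DataFrame, outcome_col: str,
                                 window: float = DEFAULT_WINDOW,
                                 step: float = DEFAULT_WINDOW,
                                 min_obs: int = DEFAULT_MIN_OBS,
                                 ) -> pd.DataFrame:
    """Per-participant rate curves over a common bin grid.

    ``records`` needs participant, dmin and ``outcome_col`` columns.  The
    grid extends to the overall maximum distance so curves are comparable
    across participants.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["participant", "bin_lo", "bin_hi",
                                     "rate", "n_obs"])
    top = float(records["dmin"].max())
    frames = []
    for p, grp in records.groupby("participant", sort=True):
        curve = sliding_window_rate(grp["dmin"], grp[outcome_col], window,
                                    step, min_obs, max_distance=top)
        curve.insert(0, "participant", p)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def cross_participant_correlation(curves: pd.DataFrame,
                                  participant_values: pd.DataFrame,
                                  value_col: str = "far",
                                  min_participants: int = 3) -> pd.DataFrame:
    """Correlate participants' bin rates with a per-participant scalar.

    For each distance bin, the Pearson correlation across participants
    between the bin's rate (e.g. hit rate at that gaze-target distance) and a
    participant-level value (e.g. overall false-alarm rate).  Bins with fewer
    than ``min_participants`` defined rates are missing.
    """
    merged = curves.merge(participant_values[["participant", value_col]],
                          on="participant")
    rows = []
    for (lo, hi), grp in merged.groupby(["bin_lo", "bin_hi"], sort=True):
        sub = grp.dropna(subset=["rate", value_col])
        if len(sub) < min_participants:
            rows.append((lo, hi, np.nan, np.nan, len(sub)))
            continue
        r, df, p = pearson(sub["rate"], sub[value_col])
        rows.append((lo, hi, r, p, len(sub)))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "r", "p",
                                       "n_participants"])


def curve_correlation(curve_a: pd.DataFrame, curve_b: pd.DataFrame,
                      min_bins: int = 3) -> float:
    """Pearson r between two rate curves over their common defined bins.

    Curves are matched on (bin_lo, bin_hi); NaN when fewer than ``min_bins``
    bins are defined in both or either curve is constant there.
    """
    merged = curve_a.merge(curve_b, on=["bin_lo", "bin_hi"],
                           suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["rate_a", "rate_b"])
    if len(merged) < min_bins:
        return float("nan")
    r, _, _ = pearson(merged["rate_a"], merged["rate_b"])
    return r
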