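"""Two-stage statistics: per-participant regressions on search scale, then
group-level t-tests, paired tests and correlations.

Performance measures (accuracy, HR, FAR, d', c) are regressed per participant
on the comparison scale *aligned to the standard scale* (x - 0.7), so the
intercept is the predicted value at the standard scale rather than at the
meaningless scale zero.  Slopes and intercepts are then tested across
participants with ordinary one-sample t-tests (all tests two-sided,
alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "GroupStat",
    "fit_aligned_regression",
    "fit_measure_regressions",
    "one_sample_test",
    "paired_test",
    "pearson",
]

STANDARD_SCALE = 0.7


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept_at_align: float
    align_at: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        return self.intercept_at_align + self.slope * (np.asarray(x) - self.align_at)


@dataclass(frozen=True)
class GroupStat:
    """One-sample (or paired) t-test summary with a 95% CI of the mean."""

    mean: float
    ci95_low: float
    ci95_high: float
    t: float
    df: int
    p: float
    reference: float
    n: int


def fit_aligned_regression(x, y, align_at: float = STANDARD_SCALE,
                           ) -> RegressionFit:
    """OLS of y on (x - align_at).

    The slope is invariant to the alignment point; the intercept is the
    fitted value at ``align_at``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct x values for a regression")
    slope, intercept = np.polyfit(x - align_at, y, 1)
    return RegressionFit(float(slope), float(intercept), align_at, len(x))


def fit_measure_regressions(sdt_summary: pd.DataFrame,
                            measures: tuple[str, ...] = (
                                "accuracy", "hr", "far", "dprime", "criterion"),
                            scale_col: str = "scale",
                            align_at: float = STANDARD_SCALE) -> pd.DataFrame:
    """Per-participant aligned regressions of each measure on scale.

    Cells with a missing measure (undefined margins) are dropped; a
    participant needs at least two remaining scale levels for that measure.
    """
    rows = []
    for p, grp in sdt_summary.groupby("participant", sort=True):
        for m in measures:
            sub = grp.dropna(subset=[m])
            if sub[scale_col].nunique() < 2:
                continue
            fit = fit_aligned_regression(sub[scale_col], sub[m], align_at)
            rows.append((p, m, fit.slope, fit.intercept_at_align, fit.n_points))
    return pd.DataFrame(rows, columns=[
        "participant", "measure", "slope", "intercept_at_standard", "n_points"])


def _t_summary(diffs: np.ndarray, reference: float) -> GroupStat:
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = len(diffs)
    if n < 2:
        raise ValueError("need n >= 2 values")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    df = n - 1
    if sd <= 1e-12 * max(1.0, abs(mean)):
        # zero variance: t undefined; report t=0, p=1 when on the reference,
        # +/-inf, p=0 otherwise
        if mean == reference:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean - reference) * np.inf), 0.0
        half = 0.0
    else:
        se = sd / np.sqrt(n)
        t = (mean - reference) / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        half = float(stats.t.ppf(0.975, df) * se)
    return GroupStat(mean, mean - half, mean + half, float(t), df, p,
                     reference, n)


def one_sample_test(values, reference: float = 0.0) -> GroupStat:
    """Two-sided one-sample t-test of the mean against ``reference``."""
    return _t_summary(np.asarray(values, dtype=float), reference)


def paired_test(values_a, values_b) -> GroupStat:
    """Paired t-test: one-sample test on a - b against 0.

    The CI of the mean difference is the "diagonal error bar" comparing the
    paired conditions.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    return _t_summary(a - b, 0.0)


def pearson(x, y) -> tuple[float, int, float]:
    """Pearson correlation with df = n - 2; NaN triple when degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), max(n - 2, 0), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), n - 2, float(p)
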