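"""Signal-detection measures for present/absent search decisions.

Each stimulus interval yields one of four outcomes from crossing true target
presence T with the observer's response R: hit (T+R+), miss (T+R-), false
alarm (T-R+), correct rejection (T-R-).  Per grouping cell we compute

    HR  = P(R+ | T+)            FAR = P(R+ | T-)
    d'  = z(HR) - z(FAR)        c   = -(z(HR) + z(FAR)) / 2

with z the standard-normal quantile.  Positive c is a conservative bias
(favouring absent responses).  Extreme rates of 0 or 1 are corrected to
0.5/N and 1 - 0.5/N before the z-transform, with N the cell's own trial
count on the relevant margin.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "categorize_outcomes",
    "correct_extreme_rate",
    "dprime_criterion",
    "summarize_sdt",
]

_CATEGORY = {
    (True, True): "hit",
    (True, False): "miss",
    (False, True): "false_alarm",
    (False, False): "correct_rejection",
}


def categorize_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach the outcome category to each interval row.

    Requires boolean ``target_present`` and ``response_present`` columns.
    """
    out = trials.copy()
    t = out["target_present"].astype(bool)
    r = out["response_present"].astype(bool)
    cat = np.where(t, np.where(r, "hit", "miss"),
                   np.where(r, "false_alarm", "correct_rejection"))
    out["category"] = cat
    out["correct"] = t == r
    return out


def correct_extreme_rate(k: int, n: int) -> float:
    """k/n with the extreme-rate correction.

    Rates of exactly 0 or 1 are replaced by 0.5/n and 1 - 0.5/n; interior
    rates are untouched.  n = 0 yields NaN (undefined cell).
    """
    if n == 0:
        return float("nan")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 0.5 / n
    if k == n:
        return 1.0 - 0.5 / n
    return k / n


def dprime_criterion(hr: float, far: float) -> tuple[float, float]:
    """d' and c from already-corrected rates in (0, 1)."""
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def summarize_sdt(outcomes: pd.DataFrame, grouping: list[str],
                  ) -> pd.DataFrame:
    """Hit rate, false-alarm rate, accuracy, d' and c per grouping cell.

    ``outcomes`` is an interval-level table with ``target_present`` and
    ``response_present``; ``grouping`` lists its grouping columns (e.g.
    ``["participant", "scale"]``).  Cells missing one margin entirely
    (no target-present or no target-absent intervals) get NaN d'/c but still
    report the defined rate and accuracy.
    """
    for col in grouping:
        if col not in outcomes.columns:
            warnings.warn(f"grouping column {col!r} absent; empty summary")
            return pd.DataFrame(columns=grouping + [
                "n_present", "n_absent", "hr", "far",
                "dprime", "criterion", "accuracy"])
    rows = []
    for key, grp in outcomes.groupby(grouping, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        t = grp["target_present"].astype(bool).to_numpy()
        r = grp["response_present"].astype(bool).to_numpy()
        n_present = int(t.sum())
        n_absent = int((~t).sum())
        hits = int((t & r).sum())
        fas = int((~t & r).sum())
        hr = correct_extreme_rate(hits, n_present) if n_present else np.nan
        far = correct_extreme_rate(fas, n_absent) if n_absent else np.nan
        if n_present and n_absent:
            dprime, criterion = dprime_criterion(hr, far)
        else:
            dprime = criterion = np.nan
        accuracy = float((t == r).mean())
        rows.append(key + (n_present, n_absent, hr, far, dprime, criterion,
                           accuracy))
    return pd.DataFrame(rows, columns=grouping + [
        "n_present", "n_absent", "hr", "far", "dprime", "criterion",
        "accuracy"])
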