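"""Type-2 (confidence) analyses for the two-interval forced-choice paradigm.

Each trial produces two present/absent decisions (one per search interval)
and a single forced choice of the interval the observer is more confident
about.  The analyses here ask how that choice relates to objective
performance:

* performance split by choice — SDT measures computed separately over chosen
  and non-chosen intervals;
* type-2 accuracy — among *discordant* trials (exactly one of the two type-1
  decisions correct), how often the correct interval was chosen, overall and
  broken down by the outcome pair (hit vs miss, correct rejection vs false
  alarm, ...);
* preference regressions — how the choice depends on the scale difference
  between the two stimuli and on which interval received the present
  response;
* interval reliability — whether performance is consistent across the two
  intervals and the choice unbiased between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sdt
from .regression import fit_aligned_regression, one_sample_test, pearson

__all__ = [
    "build_confidence_trials",
    "split_by_choice",
    "type2_accuracy",
    "type2_by_outcome_pair",
    "preference_regression",
    "present_preference_vs_hitrate",
    "interval_reliability",
]

#: outcome pairs (correct outcome, incorrect outcome) of discordant trials
OUTCOME_PAIRS = {
    ("correct_rejection", "miss"): "CR&Miss",
    ("hit", "miss"): "Hit&Miss",
    ("correct_rejection", "false_alarm"): "CR&FA",
    ("hit", "false_alarm"): "Hit&FA",
}


def build_confidence_trials(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pivot interval-level outcomes into one row per trial.

    ``outcomes`` is the categorized interval table (see
    :func:`searchconf.sdt.categorize_outcomes`) restricted to valid main
    trials; it must contain both intervals of every trial and exactly one
    chosen interval per trial.

    The returned table carries, per trial, the two intervals' scale, response,
    outcome category and correctness, the chosen interval, the ``discordant``
    flag (exactly one type-1 decision correct) and the response pattern coded
    on the *standard/comparison* axis (``"1-0"`` = present response for the
    standard stimulus only, etc.).
    """
    cols = ["participant", "trial", "interval", "scale", "is_standard",
            "target_present", "response_present", "category", "correct",
            "chosen"]
    df = outcomes[cols].copy()
    wide = df.pivot(index=["participant", "trial"], columns="interval")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    if not ((wide["chosen_1"].astype(bool) ^ wide["chosen_2"].astype(bool))
            .all()):
        raise ValueError("every trial needs exactly one chosen interval")
    wide["chosen_interval"] = np.where(wide["chosen_1"].astype(bool), 1, 2)
    wide["discordant"] = wide["correct_1"].astype(bool) ^ \
        wide["correct_2"].astype(bool)

    std_resp = np.where(wide["is_standard_1"].astype(bool),
                        wide["response_present_1"], wide["response_present_2"])
    comp_resp = np.where(wide["is_standard_1"].astype(bool),
                         wide["response_present_2"], wide["response_present_1"])
    wide["response_pattern"] = [
        f"{int(s)}-{int(c)}" for s, c in zip(std_resp, comp_resp)]
    return wide


def split_by_choice(outcomes: pd.DataFrame) -> pd.DataFrame:
    """SDT summary per participant, separately for chosen and non-chosen
    intervals.

    Returns one row per participant x chosen-status with the usual HR, FAR,
    d', c and accuracy columns.  Group-level comparisons are then paired
    tests over participants.
    """
    out = outcomes.copy()
    out["chosen"] = out["chosen"].astype(bool)
    return sdt.summarize_sdt(out, ["participant", "chosen"])


def type2_accuracy(conf_trials: pd.DataFrame) -> pd.DataFrame:
    """Confidence accuracy on discordant trials, per participant.

    A discordant trial scores correct when the chosen interval is the one
    whose type-1 decision was correct.  Also reports the fraction of trials
    that were discordant.  Participants without discordant trials get NaN.
    """
    rows = []
    for p, grp in conf_trials.groupby("participant", sort=True):
        disc = grp.loc[grp["discordant"]]
        frac = len(disc) / len(grp) if len(grp) else np.nan
        if len(disc) == 0:
            rows.append((p, np.nan, 0, frac))
            continue
        correct_interval = np.where(disc["correct_1"].astype(bool), 1, 2)
        acc = float((disc["chosen_interval"] == correct_interval).mean())
        rows.append((p, acc, len(disc), frac))
    return pd.DataFrame(rows, columns=["participant", "type2_accuracy",
                                       "n_discordant", "discordant_fraction"])


def type2_by_outcome_pair(conf_trials: pd.DataFrame,
                          min_obs: int = 6) -> pd.DataFrame:
    """Type-2 accuracy per outcome pair of discordant trials.

    Pairs are the four combinations of one correct outcome (hit or correct
    rejection) with one incorrect outcome (miss or false alarm).  A
    participant contributes to a pair only with at least ``min_obs`` trials
    in that cell.
    """
    disc = conf_trials.loc[conf_trials["discordant"]].copy()
    correct_first = disc["correct_1"].astype(bool)
    disc["correct_category"] = np.where(correct_first, disc["category_1"],
                                        disc["category_2"])
    disc["incorrect_category"] = np.where(correct_first, disc["category_2"],
                                          disc["category_1"])
    disc["pair"] = [
        OUTCOME_PAIRS[(c, i)] for c, i in
        zip(disc["correct_category"], disc["incorrect_category"])]
    disc["chose_correct"] = disc["chosen_interval"] == np.where(
        correct_first, 1, 2)
    rows = []
    for (p, pair), grp in disc.groupby(["participant", "pair"], sort=True):
        if len(grp) < min_obs:
            continue
        rows.append((p, pair, float(grp["chose_correct"].mean()), len(grp)))
    return pd.DataFrame(rows, columns=["participant", "pair", "accuracy",
                                       "n_trials"])


def _pattern_trials(conf_trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    if condition == "0-0":
        return conf_trials.loc[conf_trials["response_pattern"] == "0-0"]
    if condition == "1-0":
        return conf_trials.loc[
            conf_trials["response_pattern"].isin(["1-0", "0-1"])]
    raise ValueError("condition must be '0-0' or '1-0'")


def preference_regression(conf_trials: pd.DataFrame, condition: str,
                          coding: str = "response") -> pd.DataFrame:
    """Linear regression of the confidence choice on the scale difference.

    condition "0-0" (both responses absent):
        y = 1 when the comparison stimulus was chosen,
        x = scale(standard) - scale(comparison);
        a positive slope means the smaller stimulus attracts the choice and
        the intercept is the comparison preference at equal scales (0.5 =
        indifferent).

    condition "1-0" (exactly one present response, both orders pooled), with
    the default ``coding="response"``:
        y = 1 when the present-response interval was chosen,
        x = scale(absent-response interval) - scale(present-response
        interval); the intercept at x = 0 is the preference for present
        responses at equal scales.  ``coding="comparison"`` instead keeps the
        0-0 coding (comparison-chosen vs standard-minus-comparison scale).

    Per participant, choices are first aggregated to proportions per distinct
    x (each distinct scale difference weighted equally) and the proportions
    fitted by OLS.  Participants with fewer than two distinct x values are
    omitted.
    """
    sub = _pattern_trials(conf_trials, condition)
    std_first = sub["is_standard_1"].astype(bool)
    scale_std = np.where(std_first, sub["scale_1"], sub["scale_2"])
    scale_comp = np.where(std_first, sub["scale_2"], sub["scale_1"])
    comp_interval = np.where(std_first, 2, 1)

    if condition == "0-0" or coding == "comparison":
        x = scale_std - scale_comp
        y = (sub["chosen_interval"] == comp_interval).astype(float)
    elif coding == "response":
        present_first = sub["response_present_1"].astype(bool)
        scale_present = np.where(present_first, sub["scale_1"], sub["scale_2"])
        scale_absent = np.where(present_first, sub["scale_2"], sub["scale_1"])
        x = scale_absent - scale_present
        y = (sub["chosen_interval"] == np.where(present_first, 1, 2)
             ).astype(float)
    else:
        raise ValueError("coding must be 'response' or 'comparison'")

    tab = pd.DataFrame({"participant": sub["participant"].to_numpy(),
                        "x": np.round(x, 10), "y": y})
    rows = []
    for p, grp in tab.groupby("participant", sort=True):
        props = grp.groupby("x")["y"].mean()
        if len(props) < 2:
            continue
        fit = fit_aligned_regression(props.index.to_numpy(),
                                     props.to_numpy(), align_at=0.0)
        rows.append((p, condition, fit.slope, fit.intercept_at_align,
                     len(grp)))
    return pd.DataFrame(rows, columns=["participant", "condition", "slope",
                                       "intercept", "n_trials"])


def present_preference_vs_hitrate(preference_fits: pd.DataFrame,
                                  sdt_summary: pd.DataFrame,
                                  ) -> tuple[float, int, float]:
    """Correlate the 1-0 intercept (present-response preference) with the
    overall hit rate across participants."""
    fits = preference_fits.loc[preference_fits["condition"] == "1-0",
                               ["participant", "intercept"]]
    merged = fits.merge(sdt_summary[["participant", "hr"]], on="participant")
    return pearson(merged["intercept"], merged["hr"])


def interval_reliability(outcomes: pd.DataFrame,
                         conf_trials: pd.DataFrame) -> dict:
    """Two diagnostics of the two-interval paradigm.

    (a) across participants, the Pearson correlation between type-1 accuracy
    computed on first-interval stimuli and on second-interval stimuli;
    (b) each participant's share of interval-1 confidence choices, with a
    one-sample t-test of the shares against 0.5 (no interval bias).
    """
    acc = (outcomes.assign(correct=outcomes["target_present"].astype(bool)
                           == outcomes["response_present"].astype(bool))
           .groupby(["participant", "interval"])["correct"].mean()
           .unstack("interval"))
    r, df, p = pearson(acc[1], acc[2])
    shares = (conf_trials.groupby("participant")["chosen_interval"]
              .apply(lambda s: float((s == 1).mean())))
    test = one_sample_test(shares.to_numpy(), 0.5)
    return {
        "interval_accuracy_r": r,
        "interval_accuracy_df": df,
        "interval_accuracy_p": p,
        "interval1_choice_shares": shares,
        "interval1_share_test": test,
    }
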