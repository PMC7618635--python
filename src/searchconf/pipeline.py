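"""End-to-end pipeline: simulation -> screening -> analysis -> report.

``analyze_dataset`` reproduces the full analysis battery on any pair of
trial/fixation tables (simulated or imported): scale regressions of the
signal-detection measures, ROC/AUC and sliding-window analyses of the
minimum gaze-target distance, the chosen/non-chosen performance split,
type-2 accuracy with its outcome-pair decomposition, confidence preference
regressions and the interval-reliability diagnostics.  Every statistic in
the rendered report is recomputable from the emitted CSVs alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confidence as conf
from . import distance as dist
from . import io as sio
from . import preprocessing as prep
from . import regression as reg
from . import sdt
from .observer import DesignSpec, ObserverParams, simulate_experiment

__all__ = ["RunConfig", "simulate_to_dir", "analyze_dataset",
           "write_results", "render_report", "run_pipeline"]

log = logging.getLogger("searchconf")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    n_participants: int = 22
    seed: int = 0
    design: dict = field(default_factory=dict)      # DesignSpec overrides
    observer: dict = field(default_factory=dict)    # ObserverParams overrides
    min_obs: int = 6
    window_deg: float = 0.5
    step_deg: float = 0.5
    min_fixation_duration_ms: float = 150.0
    preference_coding: str = "response"
    pool_standard_in_scale_cells: bool = True

    def design_spec(self) -> DesignSpec:
        d = dict(self.design)
        for key in ("comparison_scales", "target_ecc_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return DesignSpec(**d)

    def observer_params(self) -> ObserverParams:
        return ObserverParams(**self.observer)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def simulate_to_dir(config: RunConfig, outdir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an experiment and persist trials.csv / fixations.csv /
    run_meta.yaml."""
    outdir = Path(outdir)
    trials, fixations = simulate_experiment(
        config.design_spec(), config.observer_params(),
        config.n_participants, config.seed)
    sio.write_table(trials, outdir / "trials.csv")
    sio.write_table(fixations, outdir / "fixations.csv")
    meta = {"seed": config.seed, "config": asdict(config)}
    (outdir / "run_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return trials, fixations


def _group_row(name: str, stat: reg.GroupStat) -> dict:
    return {"statistic": name, "mean": stat.mean, "ci95_low": stat.ci95_low,
            "ci95_high": stat.ci95_high, "t": stat.t, "df": stat.df,
            "p": stat.p, "reference": stat.reference, "n": stat.n}


def _corr_row(name: str, r: float, df: int, p: float) -> dict:
    return {"statistic": name, "mean": r, "ci95_low": np.nan,
            "ci95_high": np.nan, "t": np.nan, "df": df, "p": p,
            "reference": 0.0, "n": df + 2}


def analyze_dataset(trials: pd.DataFrame, fixations: pd.DataFrame,
                    config: RunConfig | None = None) -> dict:
    """Run the full analysis battery; returns a dict of result tables.

    Keys: validity, participant_summary, distances, sdt_by_scale,
    sdt_overall, regressions, auc, window_hr, window_choice,
    bin_correlations, curve_correlations, confidence_summary,
    type2, type2_by_pair, preference_fits, group_stats, report (str).
    """
    cfg = config or RunConfig()
    res: dict = {}

    # -- screening ---------------------------------------------------------
    trials_clean, fx_clean, distances, validity = prep.preprocess(
        trials, fixations, cfg.min_fixation_duration_ms)
    res["validity"] = validity.trial_validity
    res["participant_summary"] = validity.participant_summary
    res["fixation_removed_fraction"] = validity.fixation_removed_fraction
    res["distances"] = distances
    n_excluded = len(validity.excluded_participants)
    log.info("screening: %.1f%% fixations removed, %d participants excluded",
             100 * (validity.fixation_removed_fraction or 0), n_excluded)
    if trials_clean.empty:
        raise ValueError("no valid trials after screening")

    outcomes = sdt.categorize_outcomes(trials_clean)
    group_rows: list[dict] = []

    # -- SDT by scale + regressions ---------------------------------------
    if cfg.pool_standard_in_scale_cells:
        scale_outcomes = outcomes
    else:
        scale_outcomes = outcomes.loc[~outcomes["is_standard"]]
    sdt_by_scale = sdt.summarize_sdt(scale_outcomes, ["participant", "scale"])
    res["sdt_by_scale"] = sdt_by_scale
    regs = reg.fit_measure_regressions(sdt_by_scale)
    res["regressions"] = regs
    intercept_refs = {"accuracy": 0.5, "hr": 0.0, "far": 0.0,
                      "dprime": 0.0, "criterion": 0.0}
    for m, ref in intercept_refs.items():
        sub = regs.loc[regs["measure"] == m]
        if len(sub) >= 2:
            group_rows.append(_group_row(
                f"{m}_slope", reg.one_sample_test(sub["slope"], 0.0)))
            group_rows.append(_group_row(
                f"{m}_intercept", reg.one_sample_test(
                    sub["intercept_at_standard"], ref)))

    sdt_overall = sdt.summarize_sdt(outcomes, ["participant"])
    res["sdt_overall"] = sdt_overall

    # -- distance analyses -------------------------------------------------
    dmin_outcomes = distances.merge(
        outcomes[["participant", "trial", "interval", "category", "chosen",
                  "response_present"]],
        on=["participant", "trial", "interval"])
    hitmiss = dmin_outcomes.loc[
        dmin_outcomes["category"].isin(["hit", "miss"])].reset_index(drop=True)
    hitmiss["is_hit"] = hitmiss["category"] == "hit"
    auc_hm = dist.auc_by_participant(hitmiss, hitmiss["is_hit"], "hit_vs_miss")

    # chosen vs non-chosen: trials with exactly one hit interval
    hits = dmin_outcomes.loc[dmin_outcomes["category"] == "hit"]
    n_hits_per_trial = (dmin_outcomes.assign(
        hit=dmin_outcomes["category"] == "hit")
        .groupby(["participant", "trial"])["hit"].sum())
    one_hit = n_hits_per_trial[n_hits_per_trial == 1].reset_index()[
        ["participant", "trial"]]
    hits1 = hits.merge(one_hit, on=["participant", "trial"]).reset_index(drop=True)
    auc_ch = dist.auc_by_participant(hits1, hits1["chosen"].astype(bool),
                                     "chosen_vs_nonchosen")
    res["auc"] = pd.concat([auc_hm, auc_ch], ignore_index=True)
    for name, tab in (("auc_hit_vs_miss", auc_hm),
                      ("auc_chosen_vs_nonchosen", auc_ch)):
        vals = tab["auc"].dropna()
        if len(vals) >= 2:
            group_rows.append(_group_row(name,
                                         reg.one_sample_test(vals, 0.5)))

    # hit rate vs distance (target-present intervals only)
    present = dmin_outcomes.copy()
    present["is_hit"] = (present["category"] == "hit").astype(float)
    window_hr = dist.window_curves_by_participant(
        present.rename(columns={"is_hit": "outcome"}), "outcome",
        cfg.window_deg, cfg.step_deg, cfg.min_obs)
    res["window_hr"] = window_hr
    bin_corr = dist.cross_participant_correlation(
        window_hr, sdt_overall[["participant", "far"]], "far")
    res["bin_correlations"] = bin_corr

    # choice curve: hit intervals whose partner got an absent response
    resp = trials_clean.pivot_table(index=["participant", "trial"],
                                    columns="interval",
                                    values="response_present",
                                    aggfunc="first")
    partner_absent = []
    for _, row in hits.iterrows():
        other = 2 if row["interval"] == 1 else 1
        partner_absent.append(
            not bool(resp.loc[(row["participant"], row["trial"]), other]))
    choice_rec = hits.loc[np.asarray(partner_absent, dtype=bool)].copy()
    choice_rec["outcome"] = choice_rec["chosen"].astype(float)
    window_choice = dist.window_curves_by_participant(
        choice_rec, "outcome", cfg.window_deg, cfg.step_deg, cfg.min_obs)
    res["window_choice"] = window_choice

    # per-participant correlation between HR curve and choice curve
    curve_rs = []
    for p in window_hr["participant"].unique():
        r = dist.curve_correlation(
            window_hr.loc[window_hr["participant"] == p],
            window_choice.loc[window_choice["participant"] == p])
        curve_rs.append((p, r))
    curve_corr = pd.DataFrame(curve_rs, columns=["participant", "r"])
    res["curve_correlations"] = curve_corr
    vals = curve_corr["r"].dropna()
    if len(vals) >= 2:
        group_rows.append(_group_row("hr_choice_curve_r",
                                     reg.one_sample_test(vals, 0.0)))

    # -- confidence analyses ----------------------------------------------
    split = conf.split_by_choice(outcomes)
    res["confidence_summary"] = split
    wide = split.pivot(index="participant", columns="chosen")
    for m in ("accuracy", "hr", "far", "dprime", "criterion"):
        try:
            chosen_v = wide[(m, True)]
            non_v = wide[(m, False)]
        except KeyError:
            continue
        ok = chosen_v.notna() & non_v.notna()
        if ok.sum() >= 2:
            group_rows.append(_group_row(
                f"{m}_chosen_minus_nonchosen",
                reg.paired_test(chosen_v[ok], non_v[ok])))

    ct = conf.build_confidence_trials(outcomes)
    t2 = conf.type2_accuracy(ct)
    res["type2"] = t2
    type1_acc = sdt_overall.set_index("participant")["accuracy"]
    t2i = t2.set_index("participant")["type2_accuracy"]
    common = type1_acc.index.intersection(t2i.dropna().index)
    if len(common) >= 2:
        group_rows.append(_group_row(
            "type2_accuracy", reg.one_sample_test(t2i[common], 0.5)))
        group_rows.append(_group_row(
            "type2_minus_type1_accuracy",
            reg.paired_test(t2i[common], type1_acc[common])))
        group_rows.append(_corr_row(
            "type1_type2_accuracy_r",
            *reg.pearson(type1_acc[common], t2i[common])))
        group_rows.append(_group_row(
            "discordant_fraction",
            reg.one_sample_test(
                t2.set_index("participant")["discordant_fraction"][common],
                0.0)))

    by_pair = conf.type2_by_outcome_pair(ct, cfg.min_obs)
    res["type2_by_pair"] = by_pair
    for pair, grp in by_pair.groupby("pair"):
        if len(grp) >= 2:
            group_rows.append(_group_row(
                f"type2_{pair}", reg.one_sample_test(grp["accuracy"], 0.5)))

    pref = pd.concat([
        conf.preference_regression(ct, "0-0"),
        conf.preference_regression(ct, "1-0", cfg.preference_coding),
    ], ignore_index=True)
    res["preference_fits"] = pref
    for cond in ("0-0", "1-0"):
        sub = pref.loc[pref["condition"] == cond]
        if len(sub) >= 2:
            group_rows.append(_group_row(
                f"pref_{cond}_slope", reg.one_sample_test(sub["slope"], 0.0)))
            group_rows.append(_group_row(
                f"pref_{cond}_intercept",
                reg.one_sample_test(sub["intercept"], 0.5)))
    r, df_, p = conf.present_preference_vs_hitrate(pref, sdt_overall)
    group_rows.append(_corr_row("present_pref_vs_hr_r", r, df_, p))

    rel = conf.interval_reliability(outcomes, ct)
    group_rows.append(_corr_row("interval_accuracy_r",
                                rel["interval_accuracy_r"],
                                rel["interval_accuracy_df"],
                                rel["interval_accuracy_p"]))
    group_rows.append(_group_row("interval1_choice_share",
                                 rel["interval1_share_test"]))

    res["group_stats"] = pd.DataFrame(group_rows)
    res["report"] = render_report(res)
    return res


_REPORT_SECTIONS = [
    ("Visual search performance",
     ["accuracy_slope", "accuracy_intercept", "hr_slope", "hr_intercept",
      "far_slope", "far_intercept", "dprime_slope", "dprime_intercept",
      "criterion_slope", "criterion_intercept"]),
    ("Eye movements and search performance",
     ["auc_hit_vs_miss"]),
    ("Confidence choices and objective performance",
     ["accuracy_chosen_minus_nonchosen", "hr_chosen_minus_nonchosen",
      "far_chosen_minus_nonchosen", "dprime_chosen_minus_nonchosen",
      "criterion_chosen_minus_nonchosen", "discordant_fraction",
      "type2_accuracy", "type2_minus_type1_accuracy",
      "type1_type2_accuracy_r", "type2_CR&Miss", "type2_Hit&Miss",
      "type2_CR&FA", "type2_Hit&FA"]),
    ("Confidence, scale and response preferences",
     ["pref_0-0_slope", "pref_0-0_intercept", "pref_1-0_slope",
      "pref_1-0_intercept", "present_pref_vs_hr_r"]),
    ("Confidence choices and eye movements",
     ["auc_chosen_vs_nonchosen", "hr_choice_curve_r"]),
    ("Interval reliability",
     ["interval_accuracy_r", "interval1_choice_share"]),
]


def render_report(res: dict) -> str:
    """Markdown summary of every group-level statistic."""
    gs = res["group_stats"].set_index("statistic")
    lines = ["# Search-confidence analysis report", ""]
    removed = res.get("fixation_removed_fraction")
    if removed is not None:
        lines.append(f"Fixations removed by the 150 ms duration filter: "
                     f"{100 * removed:.2f}%")
    ps = res["participant_summary"]
    lines.append(f"Participants analysed: {int((~ps['excluded']).sum())} "
                 f"of {len(ps)} (excluded: {int(ps['excluded'].sum())}); "
                 f"mean invalid-trial fraction "
                 f"{100 * ps['invalid_fraction'].mean():.2f}%")
    lines.append("")
    for title, names in _REPORT_SECTIONS:
        rows = [n for n in names if n in gs.index]
        if not rows:
            continue
        lines.append(f"## {title}")
        lines.append("")
        for n in rows:
            row = gs.loc[n]
            if np.isnan(row["t"]):
                lines.append(
                    f"- {n}: r = {row['mean']:.3f} "
                    f"(df = {int(row['df'])}, p = {row['p']:.4g})")
            else:
                lines.append(
                    f"- {n}: {row['mean']:.3f} "
                    f"[{row['ci95_low']:.3f}, {row['ci95_high']:.3f}], "
                    f"t({int(row['df'])}) = {row['t']:.2f}, "
                    f"p = {row['p']:.4g} (vs {row['reference']:g})")
        lines.append("")
    return "\n".join(lines)


_CSV_KEYS = ["validity", "participant_summary", "distances", "sdt_by_scale",
             "sdt_overall", "regressions", "auc", "window_hr",
             "window_choice", "bin_correlations", "curve_correlations",
             "confidence_summary", "type2", "type2_by_pair",
             "preference_fits", "group_stats"]


def write_results(res: dict, outdir) -> None:
    """Persist every result table as CSV plus the markdown report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in _CSV_KEYS:
        if key in res:
            sio.write_table(res[key], outdir / f"{key}.csv")
    (outdir / "report.md").write_text(res["report"])


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> analyze -> write; deterministic given config.seed."""
    outdir = Path(outdir)
    trials, fixations = simulate_to_dir(config, outdir)
    res = analyze_dataset(trials, fixations, config)
    write_results(res, outdir)
    return res
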