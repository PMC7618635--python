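"""Type-2 confidence analyses: choice splits, type-2 accuracy, preference
regressions and interval reliability."""

import numpy as np
import pandas as pd
import pytest

import searchconf as sc
from searchconf.sdt import categorize_outcomes


def bulk_trials(scales_comp, target_std, target_comp, resp_std, resp_comp,
                chosen_std, participant="p1"):
    """Vectorized two-interval trial builder (standard always interval 1)."""
    n = len(scales_comp)
    mk = lambda arr: np.asarray(arr, dtype=bool)  # noqa: E731
    rows = {
        "participant": np.repeat(participant, 2 * n),
        "trial": np.repeat(np.arange(1, n + 1), 2),
        "interval": np.tile([1, 2], n),
        "scale": np.column_stack([np.full(n, 0.7), scales_comp]).ravel(),
        "is_standard": np.tile([True, False], n),
        "target_present": np.column_stack(
            [mk(target_std), mk(target_comp)]).ravel(),
        "response_present": np.column_stack(
            [mk(resp_std), mk(resp_comp)]).ravel(),
        "chosen": np.column_stack([mk(chosen_std), ~mk(chosen_std)]).ravel(),
    }
    df = pd.DataFrame(rows)
    df["target_x_deg"] = np.where(df["target_present"], 2.5 * df["scale"],
                                  np.nan)
    df["target_y_deg"] = np.where(df["target_present"], 0.0, np.nan)
    df["blink"] = False
    df["practice"] = False
    return df


def conf_trials_of(trials):
    return sc.build_confidence_trials(categorize_outcomes(trials))


class TestBuildConfidenceTrials:
    def test_counts_reconcile(self, small_dataset):
        trials, fixations = small_dataset
        clean, _, _, _ = sc.preprocess(trials, fixations)
        out = categorize_outcomes(clean)
        ct = sc.build_confidence_trials(out)
        n_trials = len(out) // 2
        assert len(ct) == n_trials
        assert int(out["chosen"].sum()) == n_trials          # one chosen
        assert int((~out["chosen"].astype(bool)).sum()) == n_trials

    def test_discordant_definition(self):
        # hit+miss discordant; hit+hit concordant; miss+FA concordant
        trials = bulk_trials([0.4, 0.5, 0.6],
                             target_std=[1, 1, 1], target_comp=[1, 1, 0],
                             resp_std=[1, 1, 0], resp_comp=[0, 1, 1],
                             chosen_std=[1, 1, 1])
        ct = conf_trials_of(trials)
        assert ct["discordant"].tolist() == [True, False, False]

    def test_response_pattern_coded_on_responses(self):
        trials = bulk_trials([0.4], target_std=[1], target_comp=[1],
                             resp_std=[1], resp_comp=[0], chosen_std=[1])
        ct = conf_trials_of(trials)
        assert ct["response_pattern"].iloc[0] == "1-0"


class TestSplitByChoice:
    def test_chosen_always_correct(self):
        trials = bulk_trials([0.4, 0.5],
                             target_std=[1, 1], target_comp=[0, 0],
                             resp_std=[1, 1], resp_comp=[1, 1],
                             chosen_std=[1, 1])
        split = sc.split_by_choice(categorize_outcomes(trials)) \
            .set_index("chosen")
        assert split.loc[True, "accuracy"] == 1.0
        assert split.loc[False, "accuracy"] == 0.0

    def test_detection_weighted_chooser_boosts_chosen_hr(self, small_results):
        split = small_results["confidence_summary"]
        wide = split.pivot(index="participant", columns="chosen",
                           values="hr")
        assert (wide[True] > wide[False]).all()


class TestType2Accuracy:
    def test_perfect_chooser(self):
        trials = bulk_trials([0.4] * 4,
                             target_std=[1, 1, 1, 1], target_comp=[0] * 4,
                             resp_std=[1, 1, 1, 1], resp_comp=[1] * 4,
                             chosen_std=[1, 1, 1, 1])
        t2 = sc.type2_accuracy(conf_trials_of(trials))
        assert t2["type2_accuracy"].iloc[0] == 1.0
        assert t2["discordant_fraction"].iloc[0] == 1.0

    def test_direct_count(self):
        # 4 discordant trials, correct interval chosen in 3
        trials = bulk_trials([0.4] * 4,
                             target_std=[1] * 4, target_comp=[0] * 4,
                             resp_std=[1] * 4, resp_comp=[1] * 4,
                             chosen_std=[1, 1, 1, 0])
        t2 = sc.type2_accuracy(conf_trials_of(trials))
        assert t2["type2_accuracy"].iloc[0] == pytest.approx(0.75)
        assert t2["n_discordant"].iloc[0] == 4

    def test_no_discordant_trials_missing(self):
        trials = bulk_trials([0.4], target_std=[1], target_comp=[1],
                             resp_std=[1], resp_comp=[1], chosen_std=[1])
        t2 = sc.type2_accuracy(conf_trials_of(trials))
        assert np.isnan(t2["type2_accuracy"].iloc[0])

    def test_random_chooser_at_chance(self):
        rng = np.random.default_rng(31)
        n = 10_000
        # every trial discordant (standard hit vs comparison false alarm
        # partner pattern); chooser uniform
        trials = bulk_trials(np.full(n, 0.4),
                             target_std=np.ones(n), target_comp=np.zeros(n),
                             resp_std=np.ones(n), resp_comp=np.ones(n),
                             chosen_std=rng.integers(0, 2, n))
        t2 = sc.type2_accuracy(conf_trials_of(trials))
        assert t2["n_discordant"].iloc[0] == n
        assert abs(t2["type2_accuracy"].iloc[0] - 0.5) < 0.02


class TestType2ByOutcomePair:
    def test_pair_labels_and_perfect_chooser(self):
        trials = bulk_trials(
            [0.4] * 4,
            target_std=[1, 1, 0, 1], target_comp=[1, 0, 0, 0],
            resp_std=[1, 0, 0, 1], resp_comp=[0, 0, 1, 1],
            chosen_std=[1, 0, 1, 1])
        # pairs: Hit&Miss, CR&Miss, CR&FA, Hit&FA; correct interval chosen
        pairs = sc.type2_by_outcome_pair(conf_trials_of(trials), min_obs=1)
        assert set(pairs["pair"]) == {"Hit&Miss", "CR&Miss", "CR&FA", "Hit&FA"}
        assert (pairs["accuracy"] == 1.0).all()

    def test_min_obs_excludes_sparse_cells(self):
        trials = bulk_trials([0.4] * 5,
                             target_std=[1] * 5, target_comp=[0] * 5,
                             resp_std=[1] * 5, resp_comp=[1] * 5,
                             chosen_std=[1] * 5)
        # 5 Hit&FA trials < 6 -> excluded
        pairs = sc.type2_by_outcome_pair(conf_trials_of(trials), min_obs=6)
        assert pairs.empty

    def test_pair_accuracies_aggregate_to_overall(self, small_dataset):
        trials, fixations = small_dataset
        clean, _, _, _ = sc.preprocess(trials, fixations)
        ct = sc.build_confidence_trials(categorize_outcomes(clean))
        overall = sc.type2_accuracy(ct).set_index("participant")
        pairs = sc.type2_by_outcome_pair(ct, min_obs=1)
        for p, grp in pairs.groupby("participant"):
            weighted = np.average(grp["accuracy"], weights=grp["n_trials"])
            assert weighted == pytest.approx(
                overall.loc[p, "type2_accuracy"])
            assert grp["n_trials"].sum() == overall.loc[p, "n_discordant"]


class TestPreferenceRegression:
    def test_deterministic_smaller_stimulus_chooser(self):
        scales = np.repeat([0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0], 4)
        smaller_is_std = scales > 0.7
        trials = bulk_trials(scales,
                             target_std=np.zeros_like(scales),
                             target_comp=np.zeros_like(scales),
                             resp_std=np.zeros_like(scales),
                             resp_comp=np.zeros_like(scales),
                             chosen_std=smaller_is_std)
        fit = sc.preference_regression(conf_trials_of(trials), "0-0")
        assert fit["slope"].iloc[0] > 0

    def test_deterministic_present_response_chooser(self):
        scales = np.repeat([0.4, 0.7, 1.0], 4)
        trials = bulk_trials(scales,
                             target_std=np.ones_like(scales),
                             target_comp=np.zeros_like(scales),
                             resp_std=np.ones_like(scales),
                             resp_comp=np.zeros_like(scales),
                             chosen_std=np.ones_like(scales))
        fit = sc.preference_regression(conf_trials_of(trials), "1-0")
        assert fit["intercept"].iloc[0] == pytest.approx(1.0)
        assert fit["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_random_chooser_near_indifference(self):
        rng = np.random.default_rng(13)
        n = 10_000
        scales = rng.choice([0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0], n)
        trials = bulk_trials(scales,
                             target_std=np.zeros(n), target_comp=np.zeros(n),
                             resp_std=np.zeros(n), resp_comp=np.zeros(n),
                             chosen_std=rng.integers(0, 2, n))
        fit = sc.preference_regression(conf_trials_of(trials), "0-0")
        assert abs(fit["slope"].iloc[0]) < 0.1
        assert abs(fit["intercept"].iloc[0] - 0.5) < 0.03

    def test_mirrored_01_pattern_pools_into_10(self):
        # present response on the comparison side only
        trials = bulk_trials([0.4, 1.0] * 4,
                             target_std=np.zeros(8), target_comp=np.ones(8),
                             resp_std=np.zeros(8), resp_comp=np.ones(8),
                             chosen_std=np.zeros(8))
        fit = sc.preference_regression(conf_trials_of(trials), "1-0")
        assert fit["intercept"].iloc[0] == pytest.approx(1.0)

    def test_comparison_coding_option(self):
        trials = bulk_trials([0.4, 1.0] * 4,
                             target_std=np.ones(8), target_comp=np.zeros(8),
                             resp_std=np.ones(8), resp_comp=np.zeros(8),
                             chosen_std=np.ones(8))
        fit = sc.preference_regression(conf_trials_of(trials), "1-0",
                                       coding="comparison")
        # always choosing the standard = never the comparison
        assert fit["intercept"].iloc[0] == pytest.approx(0.0)


class TestPresentPreferenceVsHitrate:
    @staticmethod
    def _tables(intercepts, hrs):
        fits = pd.DataFrame({"participant": list(range(len(intercepts))),
                             "condition": "1-0", "slope": 0.0,
                             "intercept": intercepts,
                             "n_trials": 10})
        sdt = pd.DataFrame({"participant": list(range(len(hrs))), "hr": hrs})
        return fits, sdt

    def test_identity_gives_unit_r(self):
        fits, sdt = self._tables([0.2, 0.4, 0.6, 0.8], [0.2, 0.4, 0.6, 0.8])
        r, df, _ = sc.present_preference_vs_hitrate(fits, sdt)
        assert r == pytest.approx(1.0)
        assert df == 2

    def test_anti_order_gives_negative_r(self):
        fits, sdt = self._tables([0.2, 0.4, 0.6], [0.9, 0.5, 0.1])
        r, _, _ = sc.present_preference_vs_hitrate(fits, sdt)
        assert r == pytest.approx(-1.0)


class TestIntervalReliability:
    def test_identical_interval_performance(self):
        frames = []
        rng = np.random.default_rng(2)
        for p, acc in (("a", 0.9), ("b", 0.7), ("c", 0.5)):
            n = 40
            correct = rng.uniform(size=n) < acc
            t = bulk_trials(np.full(n, 0.4),
                            target_std=np.ones(n), target_comp=np.ones(n),
                            resp_std=correct, resp_comp=correct,
                            chosen_std=np.ones(n), participant=p)
            frames.append(t)
        trials = pd.concat(frames, ignore_index=True)
        out = categorize_outcomes(trials)
        rel = sc.interval_reliability(out, sc.build_confidence_trials(out))
        assert rel["interval_accuracy_r"] == pytest.approx(1.0)

    def test_always_second_interval_chooser(self):
        n = 30
        frames = []
        for p in ("a", "b", "c"):
            frames.append(bulk_trials(
                np.full(n, 0.4), target_std=np.ones(n),
                target_comp=np.zeros(n), resp_std=np.ones(n),
                resp_comp=np.zeros(n), chosen_std=np.zeros(n),
                participant=p))
        out = categorize_outcomes(pd.concat(frames, ignore_index=True))
        rel = sc.interval_reliability(out, sc.build_confidence_trials(out))
        assert (rel["interval1_choice_shares"] == 0.0).all()
        assert rel["interval1_share_test"].p < 0.05
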