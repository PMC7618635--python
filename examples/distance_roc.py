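"""Minimum gaze-target distance: ROC/AUC and the hit-rate-vs-distance curve.

Simulates one observer, computes dmin per target-present interval and asks
whether dmin separates hits from misses (rank AUC) and how the hit rate
falls off with distance (0.5 degree bins, bins with < 6 observations
suppressed).
"""

import searchconf as sc

spec, params = sc.DesignSpec(), sc.ObserverParams()
trials, fixations = sc.simulate_experiment(spec, params, 2, seed=3)
clean, fx, distances, report = sc.preprocess(trials, fixations)

out = sc.categorize_outcomes(clean)
d = distances.merge(out[["participant", "trial", "interval", "category"]],
                    on=["participant", "trial", "interval"])
d = d[d["category"].isin(["hit", "miss"])]

hit_d = d.loc[d["category"] == "hit", "dmin"]
miss_d = d.loc[d["category"] == "miss", "dmin"]
auc = sc.rank_auc(hit_d, miss_d)
print(f"median dmin: hits {hit_d.median():.2f} deg, "
      f"misses {miss_d.median():.2f} deg")
print(f"rank AUC(hit vs miss) = {auc:.3f}")
print("  -> probability that a miss lies farther from the target than a hit;"
      "\n     0.5 would mean gaze proximity carries no information\n")

curve = sc.sliding_window_rate(d["dmin"], (d["category"] == "hit"),
                               min_obs=6)
print("hit rate by gaze-target distance (deg):")
print(curve.dropna(subset=["rate"]).to_string(index=False,
                                              float_format="%.3f"))
print(f"\nbeyond ~3 deg the rate flattens near the generative guess rate "
      f"({params.guess_rate}): far 'hits' are lucky guesses.")
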