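"""Type-2 analyses: what do confidence forced choices track?

Simulates a cohort, then scores the confidence choice against objective
performance: accuracy in chosen vs non-chosen intervals, type-2 accuracy
on discordant trials (exactly one of the two decisions correct), and the
preference regressions on the scale difference.
"""

import searchconf as sc

trials, fixations = sc.simulate_experiment(
    sc.DesignSpec(), sc.ObserverParams(), 6, seed=11)
clean, _, _, _ = sc.preprocess(trials, fixations)
out = sc.categorize_outcomes(clean)

split = sc.split_by_choice(out)
wide = split.pivot(index="participant", columns="chosen", values="accuracy")
print("accuracy, chosen vs non-chosen intervals:")
print(wide.rename(columns={True: "chosen", False: "non-chosen"})
      .round(3).to_string())
stat = sc.paired_test(wide[True], wide[False])
print(f"paired difference {stat.mean:+.3f} "
      f"[{stat.ci95_low:.3f}, {stat.ci95_high:.3f}], "
      f"t({stat.df}) = {stat.t:.2f}, p = {stat.p:.4f}\n")

ct = sc.build_confidence_trials(out)
t2 = sc.type2_accuracy(ct)
print(f"type-2 accuracy (discordant trials only): "
      f"{t2['type2_accuracy'].mean():.3f} "
      f"(chance 0.5; fraction discordant "
      f"{t2['discordant_fraction'].mean():.2f})")
print(sc.type2_by_outcome_pair(ct).groupby('pair')['accuracy'].mean()
      .round(3).to_string(), "\n")

pref00 = sc.preference_regression(ct, "0-0")
pref10 = sc.preference_regression(ct, "1-0")
print(f"0-0 trials (both 'absent'): slope on scale difference = "
      f"{pref00['slope'].mean():+.3f}  (> 0: smaller stimulus preferred)")
print(f"1-0 trials (one 'present'): intercept = "
      f"{pref10['intercept'].mean():.3f}  (> 0.5: present response "
      f"preferred at equal scales)")
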