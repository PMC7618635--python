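"""Signal-detection measures from raw present/absent decisions.

Builds a tiny outcome table by hand, applies the extreme-rate correction
and computes hit rate, false-alarm rate, d' and criterion.
"""

import pandas as pd

import searchconf as sc

# 10 target-present and 10 target-absent intervals of one observer
trials = pd.DataFrame({
    "participant": "s01",
    "trial": range(1, 21),
    "interval": 1,
    "target_present": [True] * 10 + [False] * 10,
    "response_present": [True] * 4 + [False] * 6      # 4 hits, 6 misses
                        + [True] * 1 + [False] * 9,   # 1 FA, 9 CRs
})

out = sc.categorize_outcomes(trials)
print(out["category"].value_counts().to_string(), "\n")

summary = sc.summarize_sdt(out, ["participant"]).iloc[0]
print(f"HR  = {summary['hr']:.3f}   (4/10)")
print(f"FAR = {summary['far']:.3f}   (1/10)")
print(f"d'  = {summary['dprime']:.3f}  (z(HR) - z(FAR): sensitivity)")
print(f"c   = {summary['criterion']:.3f}  (> 0: conservative, favours "
      f"'absent')")
print(f"acc = {summary['accuracy']:.3f}\n")

# rates of exactly 0 or 1 are pulled off the boundary by 0.5/N
print("extreme-rate correction: 10/10 ->", sc.correct_extreme_rate(10, 10),
      "   0/20 ->", sc.correct_extreme_rate(0, 20))
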