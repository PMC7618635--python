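"""Adaptive contrast staircase and the cumulative-Gaussian fit.

The pre-test titrates target contrast with a staircase that steps harder
after two consecutive correct left/right judgements and easier after each
error (converging on ~70.7% correct).  The 60 responses are then fitted
with P(correct) = 0.5 + 0.5 * Phi((x - mu) / sigma) and the main
experiment uses a target contrast of 1.5 * mu.
"""

import numpy as np
from scipy.stats import norm

import searchconf as sc

rng = np.random.default_rng(8)
true_mu, true_sigma = 0.05, 0.02
psychometric = lambda c: 0.5 + 0.5 * norm.cdf((c - true_mu) / true_sigma)

trace = sc.simulate_staircase(psychometric, n_trials=60, rng=rng)
print(f"staircase: {len(trace)} trials, {trace.n_reversals} reversals, "
      f"{trace.correct.mean():.2f} correct")
print("last 10 contrasts:",
      np.array2string(trace.contrast[-10:], precision=3))

fit = sc.fit_cumulative_gaussian(trace.contrast, trace.correct)
print(f"\nfit: mu = {fit.mu:.4f} (true {true_mu}), sigma = {fit.sigma:.4f}, "
      f"converged = {fit.converged}")
print(f"target contrast for the main experiment = 1.5 * mu = "
      f"{fit.target_contrast:.4f}")
print("(mu is the contrast of ~75% correct; 1.5x puts the target clearly")
print(" above threshold at the fovea but invisible in the periphery)")
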