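"""Cumulative-Gaussian fit of the pre-test contrast staircase.

The pre-test is a two-alternative left/right localization task, so the
psychometric function has a 0.5 lower asymptote:

    P(correct | contrast x) = gamma + (1 - gamma) * Phi((x - mu) / sigma)

with gamma = 0.5 by default.  The fit maximizes the trial-level Bernoulli
likelihood (60 trials are too few to bin usefully).  The experiment's target
contrast is 1.5 * mu, aiming at a contrast detectable only near the fovea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["PsychometricFit", "fit_cumulative_gaussian"]

MU_BOUNDS = (1e-6, 1.0)
SIGMA_BOUNDS = (1e-4, 1.0)
TARGET_FACTOR = 1.5


@dataclass(frozen=True)
class PsychometricFit:
    mu: float
    sigma: float
    gamma: float
    lapse: float
    target_contrast: float
    log_likelihood: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        """Proportion correct at contrast(s) x."""
        x = np.asarray(x, dtype=float)
        upper = 1.0 - self.lapse
        return self.gamma + (upper - self.gamma) * norm.cdf(
            (x - self.mu) / self.sigma)


def _nll(params: np.ndarray, x: np.ndarray, k: np.ndarray, gamma: float,
         lapse: float) -> float:
    mu, sigma = params
    p = gamma + (1.0 - lapse - gamma) * norm.cdf((x - mu) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(np.where(k, np.log(p), np.log1p(-p))))


def fit_cumulative_gaussian(contrast, correct, gamma: float = 0.5,
                            lapse: float = 0.0) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of staircase responses.

    Runs a bounded quasi-Newton search from several starting points (the
    likelihood can be multi-modal for short, adaptive-sampling runs) and
    keeps the best.  Fits where sigma is driven to its lower bound (perfect
    separation of correct and incorrect contrasts) or where the response
    data are degenerate are flagged ``converged=False``.
    """
    x = np.asarray(contrast, dtype=float)
    k = np.asarray(correct, dtype=bool)
    if len(x) != len(k) or len(x) == 0:
        raise ValueError("contrast and correct must be equal-length, nonempty")
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct contrast levels")

    spread = max(float(np.std(x)), SIGMA_BOUNDS[0] * 10)
    starts = [
        (float(np.median(x)), spread),
        (float(np.mean(x)), spread / 2),
        (float(np.quantile(x, 0.25)), spread),
        (float(np.quantile(x, 0.75)), spread),
    ]
    best = None
    for mu0, s0 in starts:
        mu0 = float(np.clip(mu0, *MU_BOUNDS))
        s0 = float(np.clip(s0, *SIGMA_BOUNDS))
        res = minimize(_nll, x0=np.array([mu0, s0]),
                       args=(x, k, gamma, lapse),
                       method="L-BFGS-B", bounds=[MU_BOUNDS, SIGMA_BOUNDS])
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = float(best.x[0]), float(best.x[1])
    degenerate = bool(k.all() or (~k).all())
    at_bound = sigma <= SIGMA_BOUNDS[0] * (1 + 1e-6) or \
        mu <= MU_BOUNDS[0] * (1 + 1e-6)
    converged = bool(best.success) and not degenerate and not at_bound
    return PsychometricFit(mu=mu, sigma=sigma, gamma=gamma, lapse=lapse,
                           target_contrast=TARGET_FACTOR * mu,
                           log_likelihood=-float(best.fun),
                           converged=converged)
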