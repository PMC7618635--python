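"""Synthetic searching observers for a two-interval confidence forced-choice
visual-search experiment.

The experiment this module emulates: on each trial the observer searches two
successively presented circular noise stimuli (a *standard* at scale 0.7 and a
*comparison* at one of seven scales 0.4–1.0; stimulus radius is
``scale x 7.5`` degrees) for a small, low-contrast target, reports target
presence/absence for each interval, and finally chooses the interval they feel
more confident about.  The generator produces the fully crossed design
(7 scales x 4 target-presence conditions x 10 repetitions = 280 main trials
per participant, preceded by practice trials) and simulates fixation
sequences, eccentricity-limited detection, guess-driven responses and
evidence-driven confidence choices with the statistical structure the analysis
pipeline assumes.

The observer model, in brief: during each 800 ms interval the observer makes
on average ~2.36 fixations; a present target is detected with probability
``(1 - lapse) * g(dmin)`` where ``dmin`` is the minimum Euclidean distance
between any fixation and the target and ``g`` is a logistic psychometric
falling through 0.5 at ``detect_d50`` degrees; absent detection, a
target-present response is a guess with a (possibly scale-dependent)
probability; confidence compares a noisy linear combination of detection
evidence and (negative) stimulus scale between the two intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "ObserverParams",
    "StaircaseTrace",
    "generate_design",
    "simulate_fixations",
    "detection_probability",
    "simulate_response",
    "simulate_confidence_choice",
    "simulate_experiment",
    "simulate_staircase",
]

#: The four target-presence patterns, coded (standard, comparison).
CONDITIONS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (0, 0))


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design parameters.

    Scales are unitless multipliers: a stimulus at scale ``s`` is a disc of
    radius ``radius_factor * s`` degrees of visual angle, with the target (when
    present) placed at an eccentricity between ``target_ecc_bounds[0] * s`` and
    ``target_ecc_bounds[1] * s`` degrees.
    """

    comparison_scales: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    standard_scale: float = 0.7
    repetitions: int = 10
    practice_trials: int = 12
    radius_factor: float = 7.5
    target_ecc_bounds: tuple[float, float] = (2.0, 5.5)
    interval_duration_ms: float = 800.0
    interstimulus_interval_ms: float = 1500.0

    def __post_init__(self) -> None:
        scales = np.asarray(self.comparison_scales, dtype=float)
        if scales.size == 0 or np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
            raise ValueError("comparison_scales must be strictly increasing and > 0")
        if not any(math.isclose(s, self.standard_scale) for s in scales):
            raise ValueError("standard_scale must be one of comparison_scales")
        lo, hi = self.target_ecc_bounds
        if not (0 < lo < hi <= self.radius_factor):
            raise ValueError(
                "target_ecc_bounds must satisfy 0 < lower < upper <= radius_factor"
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def n_main_trials(self) -> int:
        return len(self.comparison_scales) * len(CONDITIONS) * self.repetitions


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of a synthetic searching observer.

    detect_d50 : degrees
        Gaze-target distance at which detection probability is half-maximal.
    detect_slope : 1/degrees
        Steepness of the logistic detection psychometric.
    lapse : probability
        Chance of missing a perfectly foveated target.
    guess_rate : probability
        Present-response probability when nothing was detected (the
        generative false-alarm rate).
    criterion_scale_gain : probability per unit scale
        Linear change of the guess rate with (scale - standard_scale);
        negative values make the observer more conservative at larger scales.
    fixations_per_interval : count
        Long-run mean fixation count per search interval (shifted-Poisson,
        support >= 1).
    fixation_duration_mean_ms / fixation_duration_sd_ms : ms
        Gamma-distributed fixation durations (sd 0 collapses to a constant).
    fixation_spread : fraction of the stimulus radius
        Fixations are uniform (in area) over a disc of radius
        ``fixation_spread * 7.5 * scale``; 0 pins every fixation to the
        stimulus centre.
    min_uptake_duration_ms : ms
        Fixations shorter than this gather no information and cannot drive
        detection (matching the analysis-side duration filter's premise).
    conf_w_detect / conf_w_scale / conf_noise_sd
        Weights of detection evidence and of (negative) stimulus scale in the
        confidence comparison, and the per-interval Gaussian confidence noise.
    blink_prob : probability
        Per-interval probability of a blink, which invalidates the trial.
    """

    detect_d50: float = 2.0
    detect_slope: float = 4.0
    lapse: float = 0.02
    guess_rate: float = 0.14
    criterion_scale_gain: float = 0.0
    fixations_per_interval: float = 2.36
    fixation_duration_mean_ms: float = 280.0
    fixation_duration_sd_ms: float = 99.0
    fixation_spread: float = 0.7
    min_uptake_duration_ms: float = 150.0
    conf_w_detect: float = 1.0
    conf_w_scale: float = 0.5
    conf_noise_sd: float = 0.3
    blink_prob: float = 0.01

    def __post_init__(self) -> None:
        for name in ("lapse", "guess_rate", "blink_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.detect_d50 <= 0 or self.detect_slope <= 0:
            raise ValueError("detect_d50 and detect_slope must be > 0")
        if self.fixations_per_interval < 1:
            raise ValueError("fixations_per_interval must be >= 1")


TRIAL_COLUMNS = [
    "participant", "trial", "interval", "scale", "is_standard",
    "target_present", "target_x_deg", "target_y_deg",
    "response_present", "chosen", "blink", "practice",
]
FIXATION_COLUMNS = [
    "participant", "trial", "interval", "order_index",
    "x_deg", "y_deg", "duration_ms",
]


def _sample_annulus(rng: np.random.Generator, r_lo: float, r_hi: float,
                    n: int) -> np.ndarray:
    """Points with radius uniform over [r_lo, r_hi] and uniform angle.

    The radius itself (not the area density) is uniform: target eccentricity
    is equally likely anywhere in its admissible band.
    """
    r = rng.uniform(r_lo, r_hi, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_design(spec: DesignSpec, n_participants: int,
                    seed: int) -> pd.DataFrame:
    """Generate the trial table for ``n_participants`` observers.

    Returns a long-format table with one row per stimulus interval (two per
    trial) and empty ``response_present``/``chosen`` columns.  Within every
    scale x condition cell the standard/comparison presentation order is
    counterbalanced: half the repetitions standard-first, half
    comparison-first (odd repetition counts put the extra trial on the
    standard-first side).  Practice trials are flagged ``practice=True`` and
    draw a random scale and condition each.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if spec.repetitions % 2:
        warnings.warn(
            f"repetitions={spec.repetitions} is odd: exact order "
            "counterbalancing is impossible; the extra trial in each cell "
            "is presented standard-first", UserWarning)
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    ecc_lo, ecc_hi = spec.target_ecc_bounds

    for p in range(1, n_participants + 1):
        cells: list[tuple[float, tuple[int, int], bool]] = []
        for s in spec.comparison_scales:
            for cond in CONDITIONS:
                n_std_first = (spec.repetitions + 1) // 2
                for rep in range(spec.repetitions):
                    cells.append((s, cond, rep < n_std_first))
        order = rng.permutation(len(cells))
        # practice trials: random cell draw, standard-first coin flip
        practice = [
            (
                spec.comparison_scales[rng.integers(len(spec.comparison_scales))],
                CONDITIONS[rng.integers(len(CONDITIONS))],
                bool(rng.integers(2)),
            )
            for _ in range(spec.practice_trials)
        ]
        sequence = practice + [cells[i] for i in order]

        for t, (comp_scale, cond, std_first) in enumerate(sequence, start=1):
            is_practice = t <= spec.practice_trials
            present_std, present_comp = cond
            slots = [
                (spec.standard_scale, True, present_std),
                (comp_scale, False, present_comp),
            ]
            if not std_first:
                slots.reverse()
            for interval, (scale, is_std, present) in enumerate(slots, start=1):
                if present:
                    pos = _sample_annulus(rng, ecc_lo * scale, ecc_hi * scale, 1)[0]
                    tx, ty = float(pos[0]), float(pos[1])
                else:
                    tx = ty = np.nan
                rows.append((p, t, interval, scale, is_std, bool(present),
                             tx, ty, np.nan, np.nan, False, is_practice))

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_fixations(scale: float, params: ObserverParams,
                       rng: np.random.Generator,
                       radius_factor: float = 7.5) -> pd.DataFrame:
    """Simulate the fixation sequence of one search interval.

    The number of fixations is 1 + Poisson(fixations_per_interval - 1), so the
    support is >= 1 and the long-run mean equals ``fixations_per_interval``.
    Positions are uniform in area over a disc of radius
    ``fixation_spread * radius_factor * scale`` (never outside the stimulus);
    durations are gamma distributed.
    """
    lam = max(params.fixations_per_interval - 1.0, 0.0)
    n = 1 + int(rng.poisson(lam))
    spread = min(max(params.fixation_spread, 0.0), 1.0)
    r_max = spread * radius_factor * scale
    # uniform in area: radius ~ sqrt(U) * r_max
    r = np.sqrt(rng.uniform(0.0, 1.0, size=n)) * r_max
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    mean, sd = params.fixation_duration_mean_ms, params.fixation_duration_sd_ms
    if sd <= 0:
        durations = np.full(n, mean)
    else:
        shape = (mean / sd) ** 2
        durations = rng.gamma(shape, mean / shape, size=n)
    durations = np.maximum(durations, 1.0)
    return pd.DataFrame({
        "order_index": np.arange(1, n + 1),
        "x_deg": r * np.cos(theta),
        "y_deg": r * np.sin(theta),
        "duration_ms": durations,
    })


def detection_probability(dmin: float, params: ObserverParams) -> float:
    """``(1 - lapse) * g(dmin)`` with logistic ``g``, ``g(detect_d50) = 0.5``."""
    g = 1.0 / (1.0 + np.exp(params.detect_slope * (dmin - params.detect_d50)))
    return float((1.0 - params.lapse) * g)


def _guess_probability(scale: float, standard_scale: float,
                       params: ObserverParams) -> float:
    p = params.guess_rate + params.criterion_scale_gain * (scale - standard_scale)
    return float(min(max(p, 0.0), 1.0))


def simulate_response(scale: float, target_position, fixations: pd.DataFrame,
                      params: ObserverParams, rng: np.random.Generator,
                      standard_scale: float = 0.7) -> tuple[bool, bool, float]:
    """Simulate the present/absent decision for one interval.

    Returns ``(response_present, detected, detect_evidence)``.  A present
    target at minimum gaze distance ``dmin`` is detected with probability
    ``(1 - lapse) * g(dmin)``; detection forces a present response and yields
    evidence ``1 + g(dmin)`` (graded: larger when the gaze came closer).
    Without detection a present response is a guess with probability
    ``guess_rate + criterion_scale_gain * (scale - standard_scale)`` (clamped
    to [0, 1]), and the evidence is low-mean exponential noise.
    """
    if len(fixations) == 0:
        raise ValueError("simulate_response requires at least one fixation")
    detected = False
    usable = fixations.loc[
        fixations["duration_ms"] >= params.min_uptake_duration_ms]
    if (target_position is not None and len(usable) > 0
            and not np.any(np.isnan(target_position))):
        dx = usable["x_deg"].to_numpy() - target_position[0]
        dy = usable["y_deg"].to_numpy() - target_position[1]
        dmin = float(np.sqrt(dx * dx + dy * dy).min())
        if rng.uniform() < detection_probability(dmin, params):
            detected = True
    if detected:
        g = 1.0 / (1.0 + np.exp(params.detect_slope * (dmin - params.detect_d50)))
        evidence = 1.0 + float(g)
        response = True
    else:
        evidence = float(rng.exponential(0.1))
        response = bool(rng.uniform() < _guess_probability(scale, standard_scale,
                                                           params))
    return response, detected, evidence


def simulate_confidence_choice(evidence: tuple[float, float],
                               scales: tuple[float, float],
                               params: ObserverParams,
                               rng: np.random.Generator) -> int:
    """Choose the interval (1 or 2) with the larger noisy confidence signal.

    The signal is ``conf_w_detect * evidence - conf_w_scale * scale`` plus
    Gaussian noise; exact ties are broken uniformly at random.
    """
    scores = []
    for ev, sc in zip(evidence, scales):
        noise = rng.normal(0.0, params.conf_noise_sd) if params.conf_noise_sd > 0 else 0.0
        scores.append(params.conf_w_detect * ev - params.conf_w_scale * sc + noise)
    if scores[0] == scores[1]:
        return int(rng.integers(1, 3))
    return 1 if scores[0] > scores[1] else 2


def simulate_experiment(spec: DesignSpec, params: ObserverParams,
                        n_participants: int, seed: int,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generative model: design + fixations + responses + choices.

    Returns ``(trials, fixations)`` tables in the canonical long formats.
    Deterministic given ``seed``.
    """
    trials = generate_design(spec, n_participants, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    fix_frames: list[pd.DataFrame] = []
    responses = np.zeros(len(trials), dtype=bool)
    chosen = np.zeros(len(trials), dtype=bool)
    blink = np.zeros(len(trials), dtype=bool)

    # iterate trial by trial (two consecutive rows per trial)
    idx = trials.index.to_numpy()
    for start in range(0, len(trials), 2):
        i1, i2 = idx[start], idx[start + 1]
        row1, row2 = trials.loc[i1], trials.loc[i2]
        evidence, resp = [], []
        for i, row in ((i1, row1), (i2, row2)):
            fx = simulate_fixations(row["scale"], params, rng, spec.radius_factor)
            target = (
                (row["target_x_deg"], row["target_y_deg"])
                if row["target_present"] else None
            )
            r, _, ev = simulate_response(row["scale"], target, fx, params, rng,
                                         spec.standard_scale)
            resp.append(r)
            evidence.append(ev)
            fx.insert(0, "interval", row["interval"])
            fx.insert(0, "trial", row["trial"])
            fx.insert(0, "participant", row["participant"])
            fix_frames.append(fx)
            blink_here = rng.uniform() < params.blink_prob
            responses[start + (0 if i == i1 else 1)] = r
            blink[start + (0 if i == i1 else 1)] = blink_here
        choice = simulate_confidence_choice(
            (evidence[0], evidence[1]),
            (float(row1["scale"]), float(row2["scale"])),
            params, rng)
        chosen[start] = choice == 1
        chosen[start + 1] = choice == 2

    trials = trials.copy()
    trials["response_present"] = responses
    trials["chosen"] = chosen
    trials["blink"] = blink
    fixations = pd.concat(fix_frames, ignore_index=True)[FIXATION_COLUMNS]
    return trials, fixations


# ---------------------------------------------------------------------------
# Adaptive contrast staircase (pre-test)
# ---------------------------------------------------------------------------

@dataclass
class StaircaseTrace:
    """Record of one adaptive contrast staircase run.

    contrast[i] is the target contrast shown on trial i; correct[i] the
    simulated left/right response.  The rule: contrast increases after every
    error and decreases after two consecutive correct responses (the standard
    1-up-2-down rule converging on ~70.7% correct, here following the
    convention that "up" makes the task easier).
    """

    contrast: np.ndarray
    correct: np.ndarray
    n_reversals: int

    def __len__(self) -> int:
        return len(self.contrast)


def simulate_staircase(psychometric, n_trials: int = 60,
                       rng: np.random.Generator | None = None,
                       start_contrast: float = 0.5,
                       step_log10: float = 0.1,
                       halve_after_reversals: int = 2,
                       contrast_bounds: tuple[float, float] = (1e-4, 1.0),
                       ) -> StaircaseTrace:
    """Simulate the adaptive contrast staircase of the pre-test.

    ``psychometric(contrast)`` gives the probability of a correct left/right
    judgement (lower asymptote 0.5 for the two-alternative task).  Steps are
    additive in log10 contrast and halved once after the first
    ``halve_after_reversals`` reversals.  Contrast goes up (easier) after each
    error and down after two consecutive correct responses.
    """
    if rng is None:
        rng = np.random.default_rng()
    log_c = math.log10(start_contrast)
    lo, hi = math.log10(contrast_bounds[0]), math.log10(contrast_bounds[1])
    step = step_log10
    contrasts = np.empty(n_trials)
    corrects = np.empty(n_trials, dtype=bool)
    consecutive = 0
    n_reversals = 0
    last_direction = 0  # +1 up, -1 down
    for t in range(n_trials):
        c = 10.0 ** log_c
        contrasts[t] = c
        ok = bool(rng.uniform() < psychometric(c))
        corrects[t] = ok
        direction = 0
        if not ok:
            direction = +1
            consecutive = 0
        else:
            consecutive += 1
            if consecutive == 2:
                direction = -1
                consecutive = 0
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                n_reversals += 1
                if n_reversals == halve_after_reversals:
                    step = step / 2.0
            last_direction = direction
            log_c = min(max(log_c + direction * step, lo), hi)
    return StaircaseTrace(contrast=contrasts, correct=corrects,
                          n_reversals=n_reversals)
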