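import numpy as np
import pandas as pd
import pytest

import searchconf as sc


@pytest.fixture(scope="session")
def default_spec():
    return sc.DesignSpec()


@pytest.fixture(scope="session")
def default_params():
    return sc.ObserverParams()


@pytest.fixture(scope="session")
def small_dataset(default_spec, default_params):
    """Three simulated observers with default parameters (seeded)."""
    return sc.simulate_experiment(default_spec, default_params, 3, seed=7)


@pytest.fixture(scope="session")
def small_results(small_dataset):
    trials, fixations = small_dataset
    return sc.analyze_dataset(trials, fixations)


def make_fixations(points, participant="p1", trial=1, interval=1,
                   duration=250.0):
    """Build a fixation table from (x, y) pairs (all durations equal)."""
    return pd.DataFrame({
        "participant": participant, "trial": trial, "interval": interval,
        "order_index": np.arange(1, len(points) + 1),
        "x_deg": [p[0] for p in points],
        "y_deg": [p[1] for p in points],
        "duration_ms": duration,
    })


def make_trial_rows(participant, trial, *, scales=(0.7, 0.7),
                    target=(True, True), response=(True, True),
                    chosen_interval=1, standard_interval=1,
                    blink=(False, False), practice=False):
    """Two interval rows of one trial, targets (when present) at 2.5*scale."""
    rows = []
    for i in (1, 2):
        s = scales[i - 1]
        present = target[i - 1]
        rows.append({
            "participant": participant, "trial": trial, "interval": i,
            "scale": s, "is_standard": i == standard_interval,
            "target_present": present,
            "target_x_deg": 2.5 * s if present else np.nan,
            "target_y_deg": 0.0 if present else np.nan,
            "response_present": response[i - 1],
            "chosen": i == chosen_interval,
            "blink": blink[i - 1], "practice": practice,
        })
    return rows
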