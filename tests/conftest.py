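import numpy as np
import pandas as pd
import pytest

from tortmove import GeneratorConfig, Track, derive_steps, published_params, simulate_tracks


def make_track(points, times=None, temp=20.0, sex="male", animal_id="a"):
    """Build a Track from (x, y) tuples at nominal 30-min spacing."""
    n = len(points)
    if times is None:
        times = pd.date_range("2021-04-01 06:00", periods=n, freq="30min")
    xs, ys = zip(*points)
    return Track(
        animal_id, sex,
        pd.DataFrame({"timestamp": times, "x": xs, "y": ys, "temperature": temp}),
    )


def constant_steps(rng, n, mu, sd, kappa, g12, g21, segment="s0"):
    """Directly sampled two-state step records (independent of simulate_tracks)."""
    states = np.empty(n, dtype=int)
    states[0] = rng.random() < g12 / (g12 + g21)
    for t in range(1, n):
        p = g12 if states[t - 1] == 0 else 1 - g21
        states[t] = rng.random() < p
    shape = (np.asarray(mu) / np.asarray(sd)) ** 2
    scale = np.asarray(mu) / shape
    steps = rng.gamma(shape[states], scale[states])
    angles = rng.vonmises(0.0, np.asarray(kappa)[states])
    angles[0] = np.nan
    return pd.DataFrame(
        {
            "animal_id": "x", "segment_id": segment,
            "step": np.maximum(steps, 0.1), "angle": angles,
            "hour": 12.0, "cos_hour": 0.0, "sin_hour": 0.0,
            "temperature": 20.0, "sex": 1, "log_dist": 6.0,
        }
    ), states


@pytest.fixture(scope="session")
def male_preset():
    return published_params("male")


@pytest.fixture(scope="session")
def male_const_preset():
    return published_params("male", covariate_effects=False)


@pytest.fixture(scope="session")
def female_preset():
    return published_params("female")


@pytest.fixture(scope="session")
def sim_steps_male():
    """Steps derived from a 20k-step simulated male track (full preset)."""
    params = published_params("male")
    cfg = GeneratorConfig(n_males=1, n_females=0, seed=11)
    tracks, truth = simulate_tracks(params, cfg, n_steps=20_000)
    return derive_steps(tracks[0]), truth[tracks[0].animal_id]
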