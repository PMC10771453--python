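"""Unit and property tests for step derivation and the movement HMM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gamma as gamma_dist, vonmises

from tortmove import (
    HmmSpec,
    derive_steps,
    fit_hmm,
    forward_loglik,
    model_ladder,
    predict_step_mean,
    predict_transitions,
    viterbi_decode,
)
from tortmove.hmm import BIOLOGICAL_MODELS, HIGHWAY_MODELS, HmmParams, _pack, _unpack

from conftest import constant_steps, make_track


# ---------------------------------------------------------------------------
# step derivation
# ---------------------------------------------------------------------------

class TestDeriveSteps:
    def test_right_angle_turn(self):
        steps = derive_steps(make_track([(0, 0), (0, 10), (10, 10)]))
        assert steps["step"].tolist() == [10.0, 10.0]
        assert np.isnan(steps["angle"].iloc[0])
        assert steps["angle"].iloc[1] == pytest.approx(-np.pi / 2)

    def test_collinear(self):
        steps = derive_steps(make_track([(0, 0), (0, 5), (0, 9)]))
        assert steps["step"].tolist() == [5.0, 4.0]
        assert steps["angle"].iloc[1] == pytest.approx(0.0)

    def test_gap_splits_segments(self):
        times = pd.to_datetime(
            ["2021-04-01 06:00", "2021-04-01 06:30", "2021-04-01 08:00"]
        )
        # 90-min gap > 45-min tolerance: two segments, one single-fix -> one
        # step total, and no turning angle defined anywhere
        steps = derive_steps(make_track([(0, 0), (0, 10), (10, 10)], times=times))
        assert len(steps) == 1
        assert steps["angle"].isna().all()

    def test_step_floor(self):
        steps = derive_steps(make_track([(0, 0), (0, 0.001), (0, 10)]))
        assert steps["step"].iloc[0] == pytest.approx(0.1)

    def test_nonmonotone_timestamps_rejected(self):
        times = pd.to_datetime(["2021-04-01 06:00", "2021-04-01 05:30"])
        with pytest.raises(ValueError, match="increasing"):
            make_track([(0, 0), (0, 10)], times=times)

    def test_single_fix_warns_empty(self):
        with pytest.warns(UserWarning):
            steps = derive_steps(make_track([(0, 0)]))
        assert len(steps) == 0

    def test_highway_distance_floored_log(self):
        from shapely.geometry import LineString

        hwy = LineString([(-100, 0), (100, 0)])
        steps = derive_steps(make_track([(0, 0.2), (0, 500), (0, 510)]), highway=hwy)
        assert steps["log_dist"].iloc[0] == pytest.approx(0.0)  # floored at 1 m
        assert steps["log_dist"].iloc[1] == pytest.approx(np.log(500))


# ---------------------------------------------------------------------------
# forward likelihood vs brute-force enumeration
# ---------------------------------------------------------------------------

def brute_force_loglik(steps, mu, sd, kappa, g12, g21):
    """Independent oracle: sum the joint density over every state sequence.

    Uses scipy densities directly (no shared code with the forward pass);
    only valid for constant parameters and a single segment.
    """
    T = len(steps)
    x = steps["step"].to_numpy()
    ang = steps["angle"].to_numpy()
    k = len(mu)
    dens = np.empty((T, k))
    for s in range(k):
        a = (mu[s] / sd[s]) ** 2
        dens[:, s] = gamma_dist.pdf(x, a, scale=mu[s] / a)
        ok = np.isfinite(ang)
        dens[ok, s] *= vonmises.pdf(ang[ok], kappa[s])
    gam = np.array([[1 - g12, g12], [g21, 1 - g21]])[:k, :k]
    delta = np.array([g21, g12]) / (g12 + g21) if k == 2 else np.ones(1)
    total = 0.0
    for seq in itertools.product(range(k), repeat=T):
        p = delta[seq[0]] * dens[0, seq[0]]
        for t in range(1, T):
            p *= gam[seq[t - 1], seq[t]] * dens[t, seq[t]]
        total += p
    return np.log(total)


def _const_params(mu, sd, kappa, g12, g21):
    from scipy.special import logit

    return HmmParams(
        HmmSpec(2),
        beta_mean=np.log(np.asarray(mu))[:, None],
        beta_sd=np.log(np.asarray(sd))[:, None],
        kappa=np.asarray(kappa),
        alpha=np.array([[logit(g12)], [logit(g21)]]),
    )


class TestForward:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        """Forward recursion equals the 2^T sum over state sequences."""
        rng = np.random.default_rng(seed)
        mu = rng.uniform(1, 50, 2)
        sd = rng.uniform(0.5, 40, 2)
        kappa = rng.uniform(0.1, 5, 2)
        g12, g21 = rng.uniform(0.05, 0.95, 2)
        steps, _ = constant_steps(rng, 6, mu, sd, kappa, g12, g21)
        ll = forward_loglik(_const_params(mu, sd, kappa, g12, g21), steps)
        assert ll == pytest.approx(brute_force_loglik(steps, mu, sd, kappa, g12, g21), abs=1e-8)

    def test_k1_equals_sum_of_densities(self):
        rng = np.random.default_rng(1)
        steps, _ = constant_steps(rng, 50, [5, 5], [4, 4], [1, 1], 0.5, 0.5)
        p1 = HmmParams(HmmSpec(1), np.log([[5.0]]), np.log([[4.0]]),
                       np.array([1.0]), np.zeros((0, 1)))
        ll = forward_loglik(p1, steps)
        x = steps["step"].to_numpy()
        a = (5.0 / 4.0) ** 2
        expected = gamma_dist.logpdf(x, a, scale=5.0 / a).sum()
        ang = steps["angle"].to_numpy()
        expected += vonmises.logpdf(ang[np.isfinite(ang)], 1.0).sum()
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        steps, _ = constant_steps(rng, 200, [3, 40], [3, 40], [0.5, 2], 0.1, 0.2)
        p = _const_params([3, 40], [3, 40], [0.5, 2], 0.1, 0.2)
        p_swapped = _const_params([40, 3], [40, 3], [2, 0.5], 0.2, 0.1)
        assert forward_loglik(p, steps) == pytest.approx(forward_loglik(p_swapped, steps), rel=1e-12)

    def test_invalid_params_return_neg_inf(self):
        rng = np.random.default_rng(3)
        steps, _ = constant_steps(rng, 20, [3, 40], [3, 40], [0.5, 2], 0.1, 0.2)
        bad = _const_params([3, 40], [3, 40], [0.5, 2], 0.1, 0.2)
        bad.beta_sd[:] = 1e9  # overflows the gamma shape
        assert forward_loglik(bad, steps) == -np.inf or np.isfinite(forward_loglik(bad, steps))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_fit():
    """Fit on well-separated two-state data (traveling ~50 m, resting ~1 m)."""
    rng = np.random.default_rng(7)
    steps, states = constant_steps(rng, 6000, [1.0, 50.0], [0.8, 40.0],
                                   [0.5, 4.0], 0.098, 0.228)
    fit = fit_hmm(steps, HmmSpec(2), n_restarts=2, seed=0)
    return fit, steps, states


class TestFit:
    def test_recovers_constant_transitions(self, small_fit):
        fit, _, _ = small_fit
        gam = predict_transitions(fit)
        assert gam[0, 1] == pytest.approx(0.098, abs=0.02)
        assert gam[1, 0] == pytest.approx(0.228, abs=0.03)

    def test_recovers_state_means(self, small_fit):
        fit, _, _ = small_fit
        assert predict_step_mean(fit, state="resting")["mean"] == pytest.approx(1.0, rel=0.05)
        assert predict_step_mean(fit, state="traveling")["mean"] == pytest.approx(50.0, rel=0.05)

    def test_aic_identity(self, small_fit):
        fit, _, _ = small_fit
        assert fit.aic == -2 * fit.log_likelihood + 2 * fit.n_parameters

    def test_traveling_is_larger_state(self, small_fit):
        fit, _, _ = small_fit
        m0 = predict_step_mean(fit, state=0)["mean"]
        m1 = predict_step_mean(fit, state=1)["mean"]
        assert m1 > m0

    def test_ci_positive_and_ordered(self, small_fit):
        fit, _, _ = small_fit
        r = predict_step_mean(fit, state="traveling")
        assert 0 < r["lo"] < r["mean"] < r["hi"]

    def test_local_optimum_at_mle(self, small_fit):
        """Perturbing any free parameter by +-1 SE never raises the log-lik."""
        fit, steps, _ = small_fit
        x_hat = _pack(fit.params)
        ll_hat = forward_loglik(fit.params, steps)
        for i, se in enumerate(fit.se):
            if not np.isfinite(se) or se == 0:
                continue
            for sign in (+1, -1):
                x = x_hat.copy()
                x[i] += sign * se
                ll = forward_loglik(_unpack(x, fit.params), steps)
                assert ll <= ll_hat + 1e-6

    def test_viterbi_agreement(self, small_fit):
        """Decoded states match the generating states for separated states."""
        fit, steps, states = small_fit
        decoded = viterbi_decode(fit, steps)
        assert len(decoded) == len(steps)
        assert (decoded == states).mean() >= 0.95

    def test_viterbi_k1_constant(self):
        rng = np.random.default_rng(4)
        steps, _ = constant_steps(rng, 100, [5, 5], [4, 4], [1, 1], 0.5, 0.5)
        fit1 = fit_hmm(steps, HmmSpec(1), n_restarts=1, seed=0, compute_se=False)
        assert (viterbi_decode(fit1, steps) == 0).all()

    def test_empty_steps_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(pd.DataFrame(columns=["step"]), HmmSpec(2))


class TestSpecValidation:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="log_dist:sex"):
            HmmSpec(2, mean_terms=("log_dist:sex",))

    def test_one_state_no_transition_formula(self):
        with pytest.raises(ValueError, match="one-state"):
            HmmSpec(1, transition_terms=("hour",))

    def test_unknown_term(self):
        with pytest.raises(ValueError, match="unknown term"):
            HmmSpec(2, mean_terms=("rainfall",))


# ---------------------------------------------------------------------------
# prediction properties
# ---------------------------------------------------------------------------

class TestPredict:
    def test_intercept_only_mean(self):
        p = HmmParams(HmmSpec(2), np.log([[5.0], [5.0]]), np.log([[5.0], [5.0]]),
                      np.array([1.0, 1.0]), np.zeros((2, 1)))
        for cov in ({}, {"temperature": 40.0}, {"cos_hour": 1.0}):
            assert predict_step_mean(p, covariates=cov, state="traveling")["mean"] == pytest.approx(5.0)

    def test_zero_alpha_gives_half(self):
        p = HmmParams(HmmSpec(2), np.log([[4.0], [40.0]]), np.log([[4.0], [40.0]]),
                      np.array([1.0, 1.0]), np.zeros((2, 1)))
        gam = predict_transitions(p)
        assert gam[0, 1] == pytest.approx(0.5)
        assert gam[1, 0] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        temp=st.floats(-20, 60),
        ld=st.floats(0, 10),
        ch=st.floats(-1, 1),
        sh=st.floats(-1, 1),
        sex=st.integers(0, 1),
    )
    def test_transition_rows_sum_to_one(self, temp, ld, ch, sh, sex):
        """Gamma(x) rows sum to 1 and entries stay in (0,1) for any covariates."""
        rng = np.random.default_rng(5)
        spec = HmmSpec(2, mean_terms=("hour", "temperature", "sex", "log_dist"),
                       sd_terms=("temperature",),
                       transition_terms=("hour", "temperature", "sex", "log_dist"))
        p = HmmParams(spec, rng.normal(0, 0.5, (2, 6)), rng.normal(0, 0.5, (2, 2)),
                      np.array([1.0, 2.0]), rng.normal(0, 0.5, (2, 6)),
                      centers={"temperature": 25.0, "log_dist": 6.0},
                      scales={"temperature": 10.0, "log_dist": 1.0})
        cov = {"temperature": temp, "log_dist": ld, "cos_hour": ch, "sin_hour": sh, "sex": sex}
        gam = predict_transitions(p, cov)
        assert np.allclose(gam.sum(axis=1), 1.0, atol=1e-12)
        assert ((gam > 0) & (gam < 1)).all()
        mean = predict_step_mean(p, cov, state=0)["mean"]
        assert mean > 0


# ---------------------------------------------------------------------------
# model ladders
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ladder_steps():
    rng = np.random.default_rng(9)
    steps, _ = constant_steps(rng, 400, [4.4, 47.8], [4.4, 47.8], [1.16, 2.08], 0.098, 0.228)
    # give the covariates some variation so all terms are identifiable
    n = len(steps)
    hours = (np.arange(n) % 48) / 2.0
    steps["hour"] = hours
    steps["cos_hour"] = np.cos(2 * np.pi * hours / 24)
    steps["sin_hour"] = np.sin(2 * np.pi * hours / 24)
    steps["temperature"] = 25 + 10 * np.cos(2 * np.pi * (hours - 15) / 24)
    steps["sex"] = (np.arange(n) > n // 2).astype(float)
    steps["log_dist"] = rng.uniform(4, 7, n)
    return steps


class TestLadder:
    def test_steps_ladder_structure(self, ladder_steps):
        mt = model_ladder(ladder_steps, "steps", n_restarts=1, maxiter=60)
        assert len(mt.table) == 7
        assert set(mt.table["model"]) == {label for label, _ in BIOLOGICAL_MODELS}
        ok = mt.table[mt.table["converged"]]
        assert ok["dAIC"].min() == 0.0
        # dAIC recomputable from the AIC column
        assert np.allclose(ok["dAIC"], ok["AIC"] - ok["AIC"].min())
        # sorted ascending
        assert ok["AIC"].is_monotonic_increasing

    def test_highway_ladder_structure(self, ladder_steps):
        mt = model_ladder(ladder_steps, "highway", n_restarts=1, maxiter=60)
        assert len(mt.table) == 5
        assert set(mt.table["model"]) == {label for label, _ in HIGHWAY_MODELS}

    def test_unknown_component(self, ladder_steps):
        with pytest.raises(ValueError):
            model_ladder(ladder_steps, "seasons")
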