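"""GP surrogate, Matérn 5/2 kernel, expected improvement, BOpt loop."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from ecglead.hyperopt import (
    BOptTrace,
    Dimension,
    GPState,
    HyperPoint,
    SearchSpace,
    default_search_space,
    expected_improvement,
    gp_fit,
    matern52,
    propose_next,
    run_bopt,
    sample_initial,
)


def test_kernel_at_zero_distance_is_amplitude_squared():
    assert matern52([0.2, 0.4], [0.2, 0.4], 1.7, [1.0, 2.0]) == \
        pytest.approx(1.7 ** 2, abs=1e-14)


def test_kernel_hand_value_at_unit_distance():
    # (1 + √5 + 5/3) e^(−√5) ≈ 0.5240
    val = matern52([0.0], [1.0], 1.0, [1.0])
    expect = (1 + np.sqrt(5) + 5 / 3) * np.exp(-np.sqrt(5))
    assert val == pytest.approx(expect, abs=1e-12)
    assert val == pytest.approx(0.5240, abs=5e-4)


def test_kernel_monotone_decreasing_and_vanishing():
    rs = np.linspace(0, 20, 200)
    vals = [matern52([0.0], [r], 1.0, [1.0]) for r in rs]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-8


def test_kernel_ard_length_scales_weight_dimensions():
    # distance along a long-length-scale axis counts less
    near = matern52([0, 0], [1, 0], 1.0, [10.0, 0.1])
    far = matern52([0, 0], [0, 1], 1.0, [10.0, 0.1])
    assert near > far


def test_kernel_rejects_nonpositive_length_scale():
    with pytest.raises(ValueError):
        matern52([0.0], [1.0], 1.0, [0.0])


def _toy_gp(noise=1e-6):
    X = np.array([[0.1], [0.3], [0.5], [0.8]])
    y = np.sin(3 * X[:, 0])
    state = GPState(X=X, y=y, sigma_f=1.0, length_scales=np.array([0.3]),
                    noise_sd=noise, y_mean=0.0)
    state.factorize()
    return state


def test_gp_posterior_interpolates_noiseless_observations():
    state = _toy_gp(noise=1e-8)
    mu, _sd = state.posterior(state.X)
    np.testing.assert_allclose(mu, state.y, atol=1e-6)


def test_gp_posterior_reverts_to_prior_far_from_data():
    state = _toy_gp()
    mu, sd = state.posterior(np.array([[50.0]]))
    assert abs(mu[0] - state.y_mean) < 1e-6
    assert sd[0] == pytest.approx(state.sigma_f, abs=1e-6)


def test_gp_posterior_matches_dense_closed_form():
    """Independent oracle: direct dense linear algebra on ≤ 20 points."""
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, size=(12, 3))
    y = np.sin(X @ np.array([2.0, -1.0, 0.5]))
    sigma_f, ls, noise = 0.8, np.array([0.4, 0.6, 0.3]), 0.05
    state = GPState(X=X, y=y, sigma_f=sigma_f, length_scales=ls,
                    noise_sd=noise, y_mean=0.0)
    state.factorize()
    Xs = rng.uniform(0, 1, size=(5, 3))

    def k(a, b):
        return matern52(a, b, sigma_f, ls)

    K = np.array([[k(a, b) for b in X] for a in X]) + \
        (noise ** 2 + 1e-10) * np.eye(len(X))
    Ks = np.array([[k(a, b) for b in X] for a in Xs])
    Kinv = np.linalg.inv(K)
    mu_oracle = Ks @ Kinv @ y
    var_oracle = sigma_f ** 2 - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    mu, sd = state.posterior(Xs)
    np.testing.assert_allclose(mu, mu_oracle, atol=1e-8)
    np.testing.assert_allclose(sd, np.sqrt(np.maximum(var_oracle, 0)), atol=1e-8)


def test_gp_posterior_matches_sklearn_cross_check():
    """Dual route: sklearn's GP with a Matérn ν=5/2 kernel must agree."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    rng = np.random.default_rng(1)
    X = rng.uniform(0, 1, size=(10, 2))
    y = np.cos(4 * X[:, 0]) + X[:, 1]
    ls = np.array([0.5, 0.7])
    noise = 0.1
    state = GPState(X=X, y=y, sigma_f=1.0, length_scales=ls,
                    noise_sd=noise, y_mean=0.0)
    state.factorize()
    gpr = GaussianProcessRegressor(
        kernel=Matern(length_scale=ls, nu=2.5),
        alpha=noise ** 2 + 1e-10, optimizer=None, normalize_y=False)
    gpr.fit(X, y)
    Xs = rng.uniform(0, 1, size=(6, 2))
    mu_ref, sd_ref = gpr.predict(Xs, return_std=True)
    mu, sd = state.posterior(Xs)
    np.testing.assert_allclose(mu, mu_ref, atol=1e-8)
    np.testing.assert_allclose(sd, sd_ref, atol=1e-7)


def test_gp_fit_recovers_interpolant():
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 1, size=(15, 1))
    y = np.sin(6 * X[:, 0])
    state = gp_fit(X, y, seed=0)
    mu, _ = state.posterior(X)
    np.testing.assert_allclose(mu, y, atol=0.05)


def test_expected_improvement_hand_value():
    # posterior mean equal to incumbent, sd 1: EI = φ(0)
    state = _toy_gp()
    mu = np.array([0.0])
    sd = np.array([1.0])
    ei = (0.0 - mu) * norm.cdf((0.0 - mu) / sd) + sd * norm.pdf((0.0 - mu) / sd)
    assert ei[0] == pytest.approx(norm.pdf(0.0), abs=1e-12)
    assert ei[0] == pytest.approx(0.3989, abs=5e-5)


def test_expected_improvement_matches_monte_carlo():
    state = _toy_gp(noise=0.05)
    x = np.array([[0.65]])
    mu, sd = state.posterior(x)
    incumbent = float(np.min(state.posterior(state.X)[0]))
    ei = expected_improvement(state, x, incumbent)[0]
    rng = np.random.default_rng(7)
    draws = rng.normal(mu[0], sd[0], size=1_000_000)
    mc = np.maximum(incumbent - draws, 0.0)
    se = mc.std() / np.sqrt(len(mc))
    assert abs(ei - mc.mean()) < 3 * se


def test_expected_improvement_nonnegative_and_monotone_in_std():
    state = _toy_gp()
    xs = np.linspace(0, 1, 50)[:, None]
    assert np.all(expected_improvement(state, xs) >= 0)
    # larger posterior std at fixed mean raises EI: compare closed forms
    incumbent = 0.0
    ei = lambda m, s: (incumbent - m) * norm.cdf((incumbent - m) / s) \
        + s * norm.pdf((incumbent - m) / s)
    assert ei(0.5, 2.0) > ei(0.5, 1.0) > ei(0.5, 0.5)


def test_sample_initial_log_uniform_learning_rate():
    space = default_search_space(num_layers=1)
    pts = sample_initial(space, n=10_000, seed=0)
    lr = np.log10([p.decoded["learning_rate"] for p in pts])
    stat = kstest(lr, "uniform", args=(-3.0, 2.0))
    assert stat.pvalue > 0.01
    mb = {p.decoded["minibatch"] for p in pts}
    assert mb <= set(range(16, 33))
    assert {p.decoded["schedule"] for p in pts} == {"none", "piecewise"}
    again = sample_initial(space, n=5, seed=3)
    first = sample_initial(space, n=5, seed=3)
    for a, b in zip(again, first):
        np.testing.assert_array_equal(a.u, b.u)


def test_decoded_bounds_and_integrality():
    space = default_search_space(num_layers=2)
    for p in sample_initial(space, n=500, seed=1):
        d = p.decoded
        assert 10 <= d["hidden_units_1"] <= 50 and isinstance(d["hidden_units_1"], int)
        assert 1e-3 <= d["learning_rate"] <= 1e-1
        assert 0.9 <= d["beta1"] <= 0.999
        assert 0.9 <= d["beta2"] <= 1.0


def test_propose_next_respects_exploration_constraint():
    """With a deep, noise-floor-resolved basin, the proposal must leave it."""
    X = np.linspace(0.28, 0.32, 8)[:, None]     # densely sampled basin
    y = (X[:, 0] - 0.3) ** 2
    state = GPState(X=X, y=y, sigma_f=1.0, length_scales=np.array([0.2]),
                    noise_sd=0.05, y_mean=float(y.mean()))
    state.factorize()
    space = SearchSpace((Dimension("x", (0.0, 1.0)),))
    point = propose_next(state, space, seed=0)
    _, sd = state.posterior(point.u[None, :])
    assert sd[0] >= 0.8 * state.noise_sd
    assert not (0.28 <= point.decoded["x"] <= 0.32)


def test_propose_next_deterministic():
    state = _toy_gp(noise=0.02)
    space = SearchSpace((Dimension("x", (0.0, 1.0)),))
    a = propose_next(state, space, seed=5)
    b = propose_next(state, space, seed=5)
    np.testing.assert_array_equal(a.u, b.u)


def test_run_bopt_recovers_quadratic_minimum():
    space = SearchSpace((Dimension("x", (0.0, 1.0)),))
    trace = run_bopt(space, lambda p: (p.decoded["x"] - 0.3) ** 2,
                     budget=50, seed=0)
    assert len(trace) == 50
    best, val = trace.incumbent
    assert abs(best.decoded["x"] - 0.3) < 0.05
    inc = trace.incumbent_values()
    assert np.all(np.diff(inc) <= 0)


def test_run_bopt_budget_equals_initial_design():
    space = SearchSpace((Dimension("x", (0.0, 1.0)),))
    trace = run_bopt(space, lambda p: p.decoded["x"], budget=4, seed=1)
    assert len(trace) == 4


def test_run_bopt_records_failures_without_crashing():
    space = SearchSpace((Dimension("x", (0.0, 1.0)),))
    calls = {"n": 0}

    def flaky(p):
        calls["n"] += 1
        if calls["n"] == 2:
            raise RuntimeError("training blew up")
        return (p.decoded["x"] - 0.5) ** 2

    trace = run_bopt(space, flaky, budget=10, seed=2)
    assert len(trace.failures) == 1
    assert len(trace) + len(trace.failures) == 10


def test_exploration_constraint_broadens_search():
    """On a two-basin objective, the σf(x) ≥ 0.8σ rule should visit at
    least as many distinct basins as running without it."""

    def objective(p):
        x = p.decoded["x"]
        return min((x - 0.2) ** 2, 0.5 * (x - 0.8) ** 2) + 0.001 * np.sin(40 * x)

    space = SearchSpace((Dimension("x", (0.0, 1.0)),))

    def basins(trace):
        xs = np.array([p.decoded["x"] for p in trace.points])
        return np.unique(np.digitize(xs, [0.5])).size

    with_rule = run_bopt(space, objective, budget=25, seed=3, std_factor=0.8)
    without = run_bopt(space, objective, budget=25, seed=3, std_factor=0.0)
    assert basins(with_rule) >= basins(without)


def test_trace_jsonl_round_trip(tmp_path):
    space = SearchSpace((Dimension("x", (0.0, 1.0)),))
    trace = run_bopt(space, lambda p: p.decoded["x"] ** 2, budget=6, seed=4)
    path = tmp_path / "trace.jsonl"
    trace.to_jsonl(path)
    import json

    lines = [json.loads(ln) for ln in path.read_text().splitlines()]
    assert len(lines) == 6
    assert all("objective" in ln and "hyperparameters" in ln for ln in lines)
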