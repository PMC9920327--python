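"""LSTM core: initialization, forward recurrence, loss, BPTT, Adam."""

import numpy as np
import pytest

from ecglead import lstm
from ecglead.lstm import (
    Adam,
    NetworkSpec,
    TrainingConfig,
    TrainingDivergedError,
    forward,
    gradients,
    init_weights,
    load_checkpoint,
    loss,
    save_checkpoint,
    train,
)


def test_init_input_weight_variance_follows_fan_rule():
    # layer with input width 3 and 10 hidden units: var = 2/(3+40) = 2/43
    spec = NetworkSpec((10, 20))
    draws = []
    for seed in range(900):
        draws.append(init_weights(spec, seed=seed, dtype=np.float64).Wx[0].ravel())
    draws = np.concatenate(draws)
    assert draws.size > 1e5
    assert np.var(draws) == pytest.approx(2 / 43, rel=0.05)
    assert np.mean(draws) == pytest.approx(0.0, abs=0.005)
    # second layer's fan-in is the first layer's width
    w2 = init_weights(spec, seed=0, dtype=np.float64).Wx[1]
    assert w2.shape == (10, 80)


def test_init_recurrent_blocks_are_orthogonal():
    w = init_weights(NetworkSpec((12,)), seed=5, dtype=np.float64)
    for g in range(4):
        block = w.U[0][:, g * 12:(g + 1) * 12]
        np.testing.assert_allclose(block.T @ block, np.eye(12), atol=1e-8)


def test_init_gate_biases():
    w = init_weights(NetworkSpec((7, 9)), seed=1)
    for l, h in enumerate((7, 9)):
        b = w.b[l]
        np.testing.assert_array_equal(b[h:2 * h], 1.0)   # forget gate
        np.testing.assert_array_equal(b[:h], 0.0)
        np.testing.assert_array_equal(b[2 * h:], 0.0)


def test_init_deterministic_given_seed():
    a = init_weights(NetworkSpec((11, 13)), seed=9)
    b = init_weights(NetworkSpec((11, 13)), seed=9)
    for pa, pb in zip(a.params(), b.params()):
        np.testing.assert_array_equal(pa, pb)


def test_forward_zero_weights_give_zero_output(rng):
    w = init_weights(NetworkSpec((6,)), seed=0, dtype=np.float64)
    for p in w.params():
        p[...] = 0.0
    out = forward(w, rng.standard_normal((20, 3)))
    np.testing.assert_array_equal(out, 0.0)


def test_forward_matches_hand_unrolled_scalar_lstm():
    """2 time steps, 1 unit, fixed scalar weights, unrolled by hand."""
    spec = NetworkSpec((1,), input_size=1, output_size=1)
    w = init_weights(spec, seed=0, dtype=np.float64)
    wx, u, bias = 0.5, -0.3, 0.1
    w.Wx[0][...] = wx
    w.U[0][...] = u
    w.b[0][...] = bias
    w.Wout[...] = 2.0
    w.bout[...] = 0.25
    x = np.array([[1.0], [-2.0]])

    def sig(z):
        return 1 / (1 + np.exp(-z))

    h = c = 0.0
    expect = []
    for xt in (1.0, -2.0):
        zi = wx * xt + u * h + bias
        i_t, f_t, o_t = sig(zi), sig(zi), sig(zi)
        g_t = np.tanh(zi)
        c = f_t * c + i_t * g_t
        h = o_t * np.tanh(c)
        expect.append(2.0 * h + 0.25)
    out = forward(w, x)
    np.testing.assert_allclose(out.ravel(), expect, atol=1e-12)


def test_forward_gate_activations_in_range(rng):
    w = init_weights(NetworkSpec((8,)), seed=2, dtype=np.float64)
    _, cache = forward(w, rng.standard_normal((30, 3)), return_cache=True)
    for gate in ("i", "f", "o"):
        vals = cache[0][gate]
        assert np.all(vals > 0) and np.all(vals < 1)
    assert np.all(np.abs(cache[0]["g"]) < 1)


def test_forward_is_length_covariant(rng):
    """Output prefix equals output of prefix input (causal recurrence)."""
    w = init_weights(NetworkSpec((5, 4)), seed=3, dtype=np.float64)
    x = rng.standard_normal((40, 3))
    full = forward(w, x)
    prefix = forward(w, x[:17])
    np.testing.assert_allclose(full[:17], prefix, atol=1e-12)


def test_loss_hand_values(rng):
    pred = rng.standard_normal((6, 12))
    assert loss(pred, pred) == 0.0
    # S=2, R=2, all residuals 1 -> (1/4)*4 = 1
    assert loss(np.ones((2, 2)), np.zeros((2, 2))) == pytest.approx(1.0)
    target = np.zeros((6, 12))
    assert loss(2 * pred, target) == pytest.approx(4 * loss(pred, target))


def test_loss_relates_to_per_lead_rmse(rng):
    """loss = (1/2) Σ_j RMSE_j² over one sequence."""
    from ecglead.metrics import rmse

    y = rng.standard_normal((30, 12))
    yhat = y + rng.standard_normal((30, 12))
    per_lead = sum(rmse(y[:, j], yhat[:, j]) ** 2 for j in range(12))
    assert loss(yhat, y) == pytest.approx(per_lead / 2, abs=1e-10)


def test_gradients_match_finite_differences(rng):
    spec = NetworkSpec((3,), input_size=3, output_size=12)
    w = init_weights(spec, seed=0, dtype=np.float64)
    x = rng.standard_normal((5, 3))
    y = rng.standard_normal((5, 12))
    _, g = gradients(w, x, y)
    eps = 1e-6
    for p, gp in zip(w.params(), g.params()):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 12)):   # sample a few entries per tensor
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss(forward(w, x), y)
            p[idx] = orig - eps
            lm = loss(forward(w, x), y)
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            if abs(fd) > 1e-10:
                assert gp[idx] == pytest.approx(fd, rel=1e-4)
            it.iternext()


def test_gradients_zero_residual_and_batch_averaging(rng):
    w = init_weights(NetworkSpec((4,)), seed=1, dtype=np.float64)
    x = rng.standard_normal((8, 3))
    y = forward(w, x)
    _, g = gradients(w, x, y)
    for gp in g.params():
        np.testing.assert_allclose(gp, 0.0, atol=1e-14)
    y2 = rng.standard_normal((8, 12))
    _, g1 = gradients(w, x, y2)
    xb = np.stack([x, x], axis=1)
    yb = np.stack([y2, y2], axis=1)
    _, g2 = gradients(w, xb, yb)
    for a, b in zip(g1.params(), g2.params()):
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_adam_first_step_hand_value():
    """Scalar weight, g = 1, lr = 0.1: bias-corrected step ≈ −0.1."""
    spec = NetworkSpec((1,), input_size=1, output_size=1)
    w = init_weights(spec, seed=0, dtype=np.float64)
    w.bout[...] = 0.0
    cfg = TrainingConfig(minibatch=16, learning_rate=0.1, beta1=0.9,
                         beta2=0.999, epochs=1)
    opt = Adam(w, cfg)
    g = lstm.Gradients(dWx=[np.zeros_like(w.Wx[0])],
                       dU=[np.zeros_like(w.U[0])],
                       db=[np.zeros_like(w.b[0])],
                       dWout=np.zeros_like(w.Wout),
                       dbout=np.ones_like(w.bout))
    opt.step(w, g)
    # m̂ = 1, v̂ = 1 -> Δ = −lr · 1/(1 + ε) ≈ −0.1
    assert w.bout[0] == pytest.approx(-0.1, rel=1e-6)


def test_adam_zero_gradient_leaves_weights_unchanged():
    w = init_weights(NetworkSpec((3,)), seed=0, dtype=np.float64)
    before = [p.copy() for p in w.params()]
    cfg = TrainingConfig(minibatch=16, learning_rate=0.05, epochs=1)
    opt = Adam(w, cfg)
    g = lstm.Gradients(dWx=[np.zeros_like(w.Wx[0])],
                       dU=[np.zeros_like(w.U[0])],
                       db=[np.zeros_like(w.b[0])],
                       dWout=np.zeros_like(w.Wout),
                       dbout=np.zeros_like(w.bout))
    opt.step(w, g)
    for p, b in zip(w.params(), before):
        np.testing.assert_array_equal(p, b)


def test_piecewise_schedule_decays_tenfold_every_ten_epochs():
    cfg = TrainingConfig(minibatch=16, learning_rate=0.02,
                         schedule="piecewise", epochs=100)
    assert cfg.lr_at_epoch(0) == 0.02
    assert cfg.lr_at_epoch(9) == 0.02
    assert cfg.lr_at_epoch(10) == pytest.approx(0.002)
    assert cfg.lr_at_epoch(25) == pytest.approx(0.0002)
    none = TrainingConfig(minibatch=16, learning_rate=0.02, epochs=100)
    assert none.lr_at_epoch(50) == 0.02


def _linear_task(rng, n_seq=24, S=40):
    """y = fixed (3x12) matrix times x: a learnable noiseless map."""
    B = rng.standard_normal((3, 12)) * 0.5
    x = rng.standard_normal((S, n_seq, 3)).astype(np.float32)
    y = np.einsum("sbi,ij->sbj", x, B).astype(np.float32)
    return x, y


def test_train_learns_linear_task(rng):
    x, y = _linear_task(rng)
    cfg = TrainingConfig(minibatch=8, learning_rate=0.01, epochs=100, seed=0)
    _, hist = train(NetworkSpec((10,)), cfg, (x[:, :20], y[:, :20]),
                    (x[:, 20:], y[:, 20:]))
    target_rms = float(np.sqrt(np.mean(y[:, 20:] ** 2)))
    assert hist["objective"] < 0.1 * target_rms


def test_train_loss_mostly_decreases_on_noiseless_task(rng):
    x, y = _linear_task(rng)
    cfg = TrainingConfig(minibatch=24, learning_rate=0.01, epochs=100, seed=0)
    _, hist = train(NetworkSpec((10,)), cfg, (x, y))
    tl = np.asarray(hist["train_loss"])
    assert np.sum(np.diff(tl) < 0) >= 95


def test_train_zero_epochs_returns_initial_weights(rng):
    x, y = _linear_task(rng, n_seq=4, S=10)
    cfg = TrainingConfig(minibatch=2, learning_rate=0.01, epochs=0, seed=3)
    w, hist = train(NetworkSpec((5,)), cfg, (x, y), (x, y))
    ref = init_weights(NetworkSpec((5,)), seed=3)
    for a, b in zip(w.params(), ref.params()):
        np.testing.assert_array_equal(a, b)
    assert hist["train_loss"] == []
    assert "objective" in hist


def test_train_is_deterministic(rng):
    x, y = _linear_task(rng, n_seq=6, S=15)
    cfg = TrainingConfig(minibatch=4, learning_rate=0.01, epochs=5, seed=1)
    _, h1 = train(NetworkSpec((6,)), cfg, (x, y), (x, y))
    _, h2 = train(NetworkSpec((6,)), cfg, (x, y), (x, y))
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_rmse"] == h2["val_rmse"]


def test_train_divergence_guard(rng):
    x, y = _linear_task(rng, n_seq=6, S=15)
    cfg = TrainingConfig(minibatch=4, learning_rate=0.01, epochs=50, seed=0)
    # targets beyond float32 range make the loss non-finite immediately
    with pytest.raises(TrainingDivergedError):
        train(NetworkSpec((6,)), cfg, (x, 1e39 * y.astype(np.float64)))


def test_checkpoint_round_trip_is_bit_exact(tmp_path, rng):
    w = init_weights(NetworkSpec((7, 5)), seed=4)
    cfg = TrainingConfig(minibatch=20, learning_rate=0.03, epochs=10, seed=4)
    save_checkpoint(tmp_path / "ckpt.h5", w, cfg, meta={"pipeline": "abc123"})
    back, cfg2, meta = load_checkpoint(tmp_path / "ckpt.h5")
    assert back.spec == w.spec
    for a, b in zip(back.params(), w.params()):
        np.testing.assert_array_equal(a, b)
    assert cfg2 == cfg
    assert meta == {"pipeline": "abc123"}
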