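"""Synergy estimators: dataset assembly, PCA-CLME, LSTM, LOSO evaluation."""

import numpy as np
import pytest

from gaitsynergy.synergy import (
    ChannelSpec,
    LstmConfig,
    LstmSynergy,
    LstmSynergyResults,
    PcaClme,
    SequenceDataset,
    build_dataset,
    loso_evaluate,
    regression_metrics,
)
from gaitsynergy.synergy.lstm import init_params, lstm_forward, _backward
from gaitsynergy.synthetic import make_cohort

SPEC = ChannelSpec.for_task("interlimb_hip")


def _random_dataset(n_subjects=4, T=240, C=4, seed=0, target_fn=None):
    rng = np.random.default_rng(seed)
    inputs = {f"s{i}": rng.normal(size=(T, C)) for i in range(n_subjects)}
    if target_fn is None:
        target_fn = lambda X: rng.normal(size=len(X))
    targets = {s: target_fn(X) for s, X in inputs.items()}
    return SequenceDataset(spec=SPEC, inputs=inputs, targets=targets, sampling_rate=100.0)


# ---------------------------------------------------------------- datasets


def test_interlimb_input_channel_count(healthy_cohort):
    ds = build_dataset(healthy_cohort, SPEC)
    assert ds.n_channels == 4
    for s in ds.subjects:
        assert ds.inputs[s].shape[1] == 4
        assert len(ds.targets[s]) == len(ds.inputs[s])


def test_intralimb_input_channels_are_thigh_imu(healthy_cohort):
    spec = ChannelSpec.for_task("intralimb_knee")
    assert spec.input_channels == (
        "thigh_gyro_dps",
        "thigh_acc_x",
        "thigh_acc_y",
        "thigh_acc_z",
    )
    ds = build_dataset(healthy_cohort, spec)
    assert ds.n_channels == 4


def test_target_cannot_be_an_input():
    with pytest.raises(ValueError):
        ChannelSpec(task="interlimb_hip", input_channels=("hip_deg",), target_channel="hip_deg")


def test_normalization_statistics_exclude_held_out_subject():
    ds = _random_dataset(seed=1)
    train = [s for s in ds.subjects if s != "s0"]
    ds.fit_normalization(train)
    stack = np.concatenate([ds.inputs[s] for s in train])
    assert np.allclose(ds.norm_mean, stack.mean(axis=0))
    ds.apply_normalization()
    normalized = np.concatenate([ds.inputs[s] for s in train])
    assert np.allclose(normalized.mean(axis=0), 0.0, atol=1e-9)


def test_double_normalization_is_guarded():
    ds = _random_dataset(seed=2)
    ds.fit_normalization(ds.subjects)
    ds.apply_normalization()
    with pytest.raises(RuntimeError):
        ds.apply_normalization()


# ---------------------------------------------------------------- PCA-CLME


def test_pca_recovers_exact_linear_synergy():
    w = np.array([0.5, -0.2, 0.05, 0.1])
    ds = _random_dataset(seed=3, target_fn=lambda X: X @ w + 3.0)
    rep = loso_evaluate(ds, "pca", seed=0, variance_target=1.0)
    assert rep.means["rmse"] < 1e-6


def test_pca_cannot_predict_white_noise():
    r2 = []
    for seed in range(20):
        ds = _random_dataset(n_subjects=5, seed=100 + seed)
        r2.append(loso_evaluate(ds, "pca", seed=seed).means["r2"])
    assert np.mean(r2) <= 0.05


def test_full_variance_target_keeps_all_components():
    ds = _random_dataset(seed=4)
    res = PcaClme(ds, variance_target=1.0).fit()
    assert res.k == ds.n_channels + 1
    assert np.allclose(res.loadings.T @ res.loadings, np.eye(res.k), atol=1e-10)


def test_pca_affine_equivariance_in_target():
    w = np.array([1.0, 0.5, -0.3, 0.2])
    ds1 = _random_dataset(seed=5, target_fn=lambda X: X @ w)
    ds2 = _random_dataset(seed=5, target_fn=lambda X: X @ w + 7.5)
    probe = np.random.default_rng(6).normal(size=(50, 4))
    p1 = PcaClme(ds1, 1.0).fit().predict(probe)
    p2 = PcaClme(ds2, 1.0).fit().predict(probe)
    assert np.allclose(p2 - p1, 7.5, atol=1e-8)


def test_pca_prediction_at_training_mean_is_target_mean():
    ds = _random_dataset(seed=7)
    res = PcaClme(ds, 0.95).fit()
    x_mean = res.mean[:-1]
    assert res.predict(x_mean[None, :])[0] == pytest.approx(res.mean[-1], abs=1e-9)


def test_pca_linearity_of_deviations():
    ds = _random_dataset(seed=8)
    res = PcaClme(ds, 1.0).fit()
    rng = np.random.default_rng(9)
    dx = rng.normal(size=(10, 4))
    base = res.predict(res.mean[None, :-1])[0]
    p1 = res.predict(res.mean[:-1] + dx) - base
    p2 = res.predict(res.mean[:-1] + 2 * dx) - base
    assert np.allclose(p2, 2 * p1, atol=1e-8)


# ---------------------------------------------------------------- LSTM


def test_zero_weight_network_outputs_its_bias():
    p = {k: np.zeros_like(v) for k, v in init_params(4, 1, np.random.default_rng(0)).items()}
    p["by"][:] = 2.5
    X = np.random.default_rng(1).normal(size=(20, 4))
    assert np.allclose(lstm_forward(p, X), 2.5)


def test_forward_matches_hand_evaluated_gate_equations():
    # scalar network: independent hand evaluation of the recurrence
    p = init_params(1, 1, np.random.default_rng(2))
    for k, v in p.items():
        p[k] = np.round(v, 2)
    X = np.array([[0.5], [-1.0], [2.0]])
    got = lstm_forward(p, X)

    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    h = s = 0.0
    expect = []
    for x in X[:, 0]:
        f = sig(p["Wx"][0, 0] * x + p["Wh"][0, 0] * h + p["b"][0])
        i = sig(p["Wx"][1, 0] * x + p["Wh"][1, 0] * h + p["b"][1])
        o = sig(p["Wx"][2, 0] * x + p["Wh"][2, 0] * h + p["b"][2])
        g = np.tanh(p["Wx"][3, 0] * x + p["Wh"][3, 0] * h + p["b"][3])
        s = g * i + s * f
        h = np.tanh(s) * o
        expect.append(p["Wy"][0, 0] * h + p["by"][0])
    assert np.allclose(got, expect, atol=1e-12)


def test_hidden_state_is_bounded_by_construction():
    rng = np.random.default_rng(3)
    p = init_params(2, 6, rng)
    for k in p:
        p[k] = p[k] * 10.0  # extreme weights still cannot break the bound
    X = rng.normal(size=(1, 50, 2))
    _, cache = lstm_forward(p, X, return_states=True)
    for step in cache:
        h = step[-1]
        assert np.all(np.abs(h) <= 1.0 + 1e-12)


def test_analytic_gradients_match_finite_differences():
    rng = np.random.default_rng(4)
    p = init_params(3, 4, rng)
    X = rng.normal(size=(2, 7, 3))
    Y = rng.normal(size=(2, 7))
    preds, cache = lstm_forward(p, X, return_states=True)
    grads = _backward(p, X, Y, preds, cache)

    def loss():
        return float(np.mean((lstm_forward(p, X) - Y) ** 2))

    eps = 1e-6
    for key in p:
        flat = p[key].reshape(-1)
        for idx in range(0, flat.size, max(1, flat.size // 4)):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            num = (up - down) / (2 * eps)
            ana = grads[key].reshape(-1)[idx]
            assert ana == pytest.approx(num, rel=1e-3, abs=1e-7)


def test_training_is_bit_reproducible():
    ds = _random_dataset(n_subjects=3, T=120, seed=5)
    cfg = LstmConfig(hidden=4, epochs=2, window=60, batch_size=2)
    r1 = LstmSynergy(ds, cfg).fit(seed=9)
    r2 = LstmSynergy(ds, cfg).fit(seed=9)
    for k in r1.params:
        assert np.array_equal(r1.params[k], r2.params[k])


def test_constant_zero_target_is_learned():
    ds = _random_dataset(n_subjects=3, T=200, seed=6, target_fn=lambda X: np.zeros(len(X)))
    cfg = LstmConfig(hidden=6, epochs=10, window=100, batch_size=4, learning_rate=0.01)
    res = LstmSynergy(ds, cfg).fit(seed=0)
    preds = res.predict(ds.inputs["s0"])
    assert np.max(np.abs(preds)) < 0.5


def test_prediction_rejects_wrong_channel_count():
    res = LstmSynergyResults(model=None, params=init_params(3, 2, np.random.default_rng(0)))
    with pytest.raises(ValueError):
        res.predict(np.zeros((10, 5)))


# ---------------------------------------------------------------- evaluation


def test_metrics_match_brute_force_formulas():
    rng = np.random.default_rng(10)
    for _ in range(200):
        truth = rng.normal(size=40)
        pred = rng.normal(size=40)
        m = regression_metrics(truth, pred)
        err = pred - truth
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean(err**2)), abs=1e-12)
        assert m["mae"] == pytest.approx(np.mean(np.abs(err)), abs=1e-12)
        sst = np.sum((truth - truth.mean()) ** 2)
        assert m["r2"] == pytest.approx(1 - np.sum(err**2) / sst, abs=1e-10)
        assert m["pearson"] == pytest.approx(np.corrcoef(truth, pred)[0, 1], abs=1e-12)


def test_loso_report_has_one_session_per_subject():
    ds = _random_dataset(n_subjects=8, T=150, seed=11)
    rep = loso_evaluate(ds, "pca", seed=0)
    assert len(rep.sessions) == 8
    summary = rep.summary()
    assert "mean" in summary.index
    assert len(summary) == 9


def test_loso_session_failure_names_the_subject():
    ds = _random_dataset(n_subjects=3, T=2, seed=12)  # too short to fit
    with pytest.raises(RuntimeError, match="s0"):
        loso_evaluate(ds, "pca", seed=0)


def test_loso_rejects_prenormalized_dataset():
    ds = _random_dataset(seed=13)
    ds.fit_normalization(ds.subjects)
    ds.apply_normalization()
    with pytest.raises(ValueError):
        loso_evaluate(ds, "pca", seed=0)
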