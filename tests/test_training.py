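"""Training protocol: schedule, EMA, stochastic depth, gradient noise,
early stopping, determinism, and the ensemble combiner."""

import numpy as np
import pytest

from dualscreen.model import EncoderSpec, MultitaskNetwork, MultitaskTextModel
from dualscreen.training import (
    AdamW,
    EMAState,
    TrainConfig,
    cosine_lr,
    early_stop,
    ema_update,
    ensemble_predict,
    inject_gradient_noise,
    stochastic_depth_mask,
)


# ---------------------------------------------------------------------------
# cosine annealing
# ---------------------------------------------------------------------------

def test_cosine_lr_endpoints_and_midpoint():
    cfg = TrainConfig()  # lr_max 1e-5, lr_min 1e-6, T=35
    assert cosine_lr(0, cfg) == pytest.approx(1e-5)
    assert cosine_lr(cfg.epochs, cfg) == pytest.approx(1e-6)
    cfg_even = TrainConfig(epochs=34)
    assert cosine_lr(17, cfg_even) == pytest.approx(5.5e-6)


def test_cosine_lr_monotone_nonincreasing():
    cfg = TrainConfig()
    values = [cosine_lr(t, cfg) for t in range(cfg.epochs + 1)]
    assert all(a >= b - 1e-18 for a, b in zip(values, values[1:]))


def test_cosine_lr_rejects_out_of_range():
    cfg = TrainConfig()
    with pytest.raises(ValueError):
        cosine_lr(-1, cfg)
    with pytest.raises(ValueError):
        cosine_lr(cfg.epochs + 1, cfg)


# ---------------------------------------------------------------------------
# gradient noise
# ---------------------------------------------------------------------------

def test_gradient_noise_zero_scale_is_identity(rng):
    grads = {"w": np.ones((3, 3))}
    out = inject_gradient_noise(grads, 0.0, rng)
    np.testing.assert_array_equal(out["w"], grads["w"])


def test_gradient_noise_is_zero_mean(rng):
    grads = {"w": np.zeros(10_000)}
    out = inject_gradient_noise(grads, 1e-5, rng)
    assert abs(out["w"].mean()) < 3e-7  # 3 * scale / sqrt(n) margin
    assert out["w"].std() == pytest.approx(1e-5, rel=0.05)


def test_gradient_noise_reproducible():
    a = inject_gradient_noise({"w": np.zeros(5)}, 1e-5, np.random.default_rng(7))["w"]
    b = inject_gradient_noise({"w": np.zeros(5)}, 1e-5, np.random.default_rng(7))["w"]
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# EMA
# ---------------------------------------------------------------------------

def test_ema_fixed_point():
    state = EMAState(shadow={"w": np.full(3, 2.0)}, decay=0.999)
    ema_update(state, {"w": np.full(3, 2.0)})
    np.testing.assert_allclose(state.shadow["w"], 2.0)


def test_ema_single_step_value():
    state = EMAState(shadow={"w": np.zeros(1)}, decay=0.999)
    ema_update(state, {"w": np.ones(1)})
    assert state.shadow["w"][0] == pytest.approx(0.001)


def test_ema_k_steps_match_closed_form():
    beta, k, s0, c = 0.97, 40, 5.0, -2.0
    state = EMAState(shadow={"w": np.full(1, s0)}, decay=beta)
    for _ in range(k):
        ema_update(state, {"w": np.full(1, c)})
    expected = s0 * beta**k + c * (1 - beta**k)
    assert state.shadow["w"][0] == pytest.approx(expected, abs=1e-12)


def test_ema_shape_mismatch_errors():
    state = EMAState(shadow={"w": np.zeros(2)}, decay=0.9)
    with pytest.raises(ValueError):
        ema_update(state, {"w": np.zeros(3)})


def test_ema_stays_in_convex_hull(rng):
    values = rng.normal(size=(50, 4))
    state = EMAState(shadow={"w": values[0].copy()}, decay=0.9)
    for v in values[1:]:
        ema_update(state, {"w": v})
        lo = np.minimum(values.min(axis=0), values[0])
        hi = np.maximum(values.max(axis=0), values[0])
        assert np.all(state.shadow["w"] >= lo - 1e-12)
        assert np.all(state.shadow["w"] <= hi + 1e-12)


# ---------------------------------------------------------------------------
# stochastic depth
# ---------------------------------------------------------------------------

def test_stochastic_depth_rate_zero_keeps_all(rng):
    assert stochastic_depth_mask(6, 0.0, rng).tolist() == [1] * 6


def test_stochastic_depth_empirical_rate(rng):
    draws = np.array([stochastic_depth_mask(1, 0.1, rng)[0] for _ in range(10_000)])
    assert abs((1 - draws).mean() - 0.1) < 0.01


def test_evaluation_runs_full_depth(strong_split):
    """predict() must not skip layers: identical outputs across calls even
    though training-time forward passes draw depth masks."""
    model = MultitaskTextModel(strong_split)
    net = MultitaskNetwork(model.encoder_spec, seed=0)
    ids, mask = model.encode_records(strong_split.validation[:8])
    a = net.predict(ids, mask)
    b = net.predict(ids, mask)
    np.testing.assert_array_equal(a.y_phq_reg, b.y_phq_reg)
    np.testing.assert_array_equal(a.y_phq_cls, b.y_phq_cls)


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

def test_early_stop_never_fires_while_improving():
    assert not early_stop([0.1, 0.2, 0.3, 0.4], patience=3)


def test_early_stop_walks_the_rule():
    metric = [0.5, 0.6, 0.6, 0.6, 0.6]
    assert not early_stop(metric[:4], patience=3)
    assert early_stop(metric, patience=3)


def test_early_stop_patience_one_is_immediate():
    assert early_stop([0.5, 0.5], patience=1)
    assert early_stop([0.5, 0.4], patience=1)


# ---------------------------------------------------------------------------
# full training runs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def quick_cfg():
    return TrainConfig.desk_scale(seed=3, epochs=4, patience=4)


def test_train_history_lr_follows_schedule(strong_split, quick_cfg):
    res = MultitaskTextModel(strong_split).fit(quick_cfg)
    for t, lr in zip(res.history.epochs, res.history.lr):
        assert lr == pytest.approx(cosine_lr(t, quick_cfg))


def test_train_deterministic_under_seed(strong_split, quick_cfg):
    a = MultitaskTextModel(strong_split).fit(quick_cfg)
    b = MultitaskTextModel(strong_split).fit(quick_cfg)
    assert a.history.train_loss == b.history.train_loss
    assert a.history.val_f1_mean == b.history.val_f1_mean
    sa, sb = a.network.state_dict(), b.network.state_dict()
    for k in sa:
        np.testing.assert_array_equal(sa[k], sb[k])


def test_train_keeps_best_validation_checkpoint(strong_split):
    cfg = TrainConfig.desk_scale(seed=1, epochs=6, patience=2)
    model = MultitaskTextModel(strong_split)
    res = model.fit(cfg)
    hist = res.history
    assert hist.best_epoch == int(np.argmax(hist.val_f1_mean))
    # re-evaluating the returned network reproduces the best epoch's metric
    ids, mask = model.encode_records(strong_split.validation)
    out = res.network.predict(ids, mask)
    from dualscreen.training import _screen_f1

    phq = np.array([r.phq9 for r in strong_split.validation], dtype=float)
    gad = np.array([r.gad7 for r in strong_split.validation], dtype=float)
    f1 = 0.5 * (_screen_f1(out.y_phq_reg, phq) + _screen_f1(out.y_gad_reg, gad))
    assert f1 == pytest.approx(max(hist.val_f1_mean), abs=1e-12)


def test_single_task_fit_monitors_its_own_task(strong_split, quick_cfg):
    res = MultitaskTextModel(strong_split).fit(quick_cfg, tasks="phq9")
    assert res.history.val_f1_mean == res.history.val_f1_phq
    res_g = MultitaskTextModel(strong_split).fit(quick_cfg, tasks="gad7")
    assert res_g.history.val_f1_mean == res_g.history.val_f1_gad


def test_training_losses_stay_finite_even_at_extreme_lr():
    # Adam-normalised updates keep the objective finite; the probability
    # clipping guards log(0) in the cross-entropy
    from dualscreen.synthetic import GeneratorConfig, generate_corpus
    from dualscreen.corpus import stratified_split

    corpus = generate_corpus(GeneratorConfig.strong_signal(n_records=60, seed=0))
    split = stratified_split(corpus, seed=0)
    cfg = TrainConfig.desk_scale(seed=0, epochs=3, lr_max=10.0, lr_min=10.0)
    res = MultitaskTextModel(split).fit(cfg)
    assert np.isfinite(res.history.train_loss).all()


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

def _two_nets():
    spec = EncoderSpec.tiny(vocab_size=40, max_len=16)
    return MultitaskNetwork(spec, seed=0), MultitaskNetwork(spec, seed=1)


def test_ensemble_single_model_is_identity():
    net, _ = _two_nets()
    ids = np.array([[3, 4, 5]])
    mask = np.ones_like(ids)
    solo = net.predict(ids, mask)
    ens = ensemble_predict([net], ids, mask)
    np.testing.assert_allclose(ens.y_phq_reg, solo.y_phq_reg, atol=1e-12)
    np.testing.assert_allclose(ens.y_gad_cls, solo.y_gad_cls, atol=1e-12)


def test_ensemble_identical_members_idempotent():
    net, _ = _two_nets()
    ids = np.array([[3, 4, 5]])
    mask = np.ones_like(ids)
    solo = net.predict(ids, mask)
    ens = ensemble_predict([net, net], ids, mask)
    np.testing.assert_allclose(ens.y_phq_cls, solo.y_phq_cls, atol=1e-12)


def test_ensemble_averages_regression():
    net_a, net_b = _two_nets()
    ids = np.array([[3, 4, 5]])
    mask = np.ones_like(ids)
    a, b = net_a.predict(ids, mask), net_b.predict(ids, mask)
    ens = ensemble_predict([net_a, net_b], ids, mask, weights=[0.5, 0.5])
    np.testing.assert_allclose(ens.y_phq_reg, 0.5 * (a.y_phq_reg + b.y_phq_reg), atol=1e-12)
    np.testing.assert_allclose(ens.y_phq_cls.sum(axis=1), 1.0, atol=1e-12)


def test_ensemble_rejects_bad_inputs():
    net, _ = _two_nets()
    ids = np.array([[3]])
    with pytest.raises(ValueError):
        ensemble_predict([], ids, np.ones_like(ids))
    with pytest.raises(ValueError):
        ensemble_predict([net], ids, np.ones_like(ids), weights=[0.5])
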