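"""Network wiring: GELU, parameter counts, loss closed forms, determinism."""

import numpy as np
import pytest
from scipy.special import erf

from eegsnet._autodiff import Tensor
from eegsnet.model import (
    EEGSNet,
    ModelConfig,
    compute_loss,
    count_parameters,
    gelu,
)
from eegsnet.nn import Adam, BiLSTM, Linear, clip_grad_norm


def micro_config(seed: int = 0, lstm_layers: int = 2) -> ModelConfig:
    """Smallest legal config — keeps wiring tests fast."""
    return ModelConfig(
        conv_channels=(4, 4, 8, 8, 16),
        lstm_hidden=16,
        feature_dim=16,
        lstm_layers=lstm_layers,
        seed=seed,
    )


rng = np.random.default_rng(1)


# --- GELU ------------------------------------------------------------------

def test_gelu_closed_forms():
    assert gelu(0.0) == 0.0
    assert gelu(10.0) == pytest.approx(10.0, abs=1e-6)
    # independent Φ(-1) via erf
    phi = 0.5 * (1.0 + erf(-1.0 / np.sqrt(2.0)))
    assert gelu(-1.0) == pytest.approx(-phi, abs=1e-12)
    assert gelu(-1.0) == pytest.approx(-0.15865525393145707, abs=1e-9)


# --- parameter counting ----------------------------------------------------

def test_bilstm_parameter_count_matches_gate_arithmetic():
    """2-layer bidirectional LSTM, input 64, hidden 128: 591,872 scalars."""
    lstm = BiLSTM(64, 128, 2, np.random.default_rng(0))
    n = sum(p.data.size for p in lstm.parameters())
    assert n == 2 * 4 * (64 + 128 + 1) * 128 + 2 * 4 * (256 + 128 + 1) * 128 == 591_872


def test_dense_head_parameter_count():
    head = Linear(256, 5, np.random.default_rng(0))
    assert sum(p.data.size for p in head.parameters()) == 256 * 5 + 5 == 1285


def test_default_config_hits_parameter_budget():
    n = count_parameters(ModelConfig())
    assert 550_000 <= n <= 650_000


def test_config_validation_rejects_residual_mismatch():
    with pytest.raises(ValueError, match="residual"):
        ModelConfig(conv_channels=(16, 32, 32, 32, 64))


def test_config_validation_rejects_bad_feature_dim():
    with pytest.raises(ValueError, match="feature_dim"):
        ModelConfig(conv_channels=(16, 16, 32, 32, 48))


# --- forward passes --------------------------------------------------------

@pytest.fixture(scope="module")
def micro_model():
    return EEGSNet(micro_config())


@pytest.fixture(scope="module")
def batch():
    return rng.random((2, 10, 76, 60, 3)).astype(np.float32)


def test_features_have_configured_width(micro_model):
    imgs = rng.random((3, 76, 60, 3)).astype(np.float32)
    f = micro_model.features(imgs)
    assert f.shape == (3, 16)
    assert np.isfinite(f.data).all()


def test_all_zero_image_gives_finite_features(micro_model):
    f = micro_model.features(np.zeros((1, 76, 60, 3), dtype=np.float32))
    assert np.isfinite(f.data).all()


def test_sequence_probabilities_normalise(micro_model, batch):
    probs, aux = micro_model.forward(batch, training=True)
    assert probs.shape == (20, 5)
    np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
    assert (probs.data > 0).all()
    np.testing.assert_allclose(aux.data.sum(axis=1), 1.0, atol=1e-6)


def test_evaluation_mode_is_pure_and_dropout_free(micro_model, batch):
    p1, aux1 = micro_model.forward(batch, training=False)
    p2, aux2 = micro_model.forward(batch, training=False)
    np.testing.assert_array_equal(p1.data, p2.data)
    assert aux1 is None and aux2 is None  # auxiliary head removed at test time


def test_same_seed_reproduces_outputs(batch):
    a, _ = EEGSNet(micro_config(seed=5)).forward(batch, training=False)
    b, _ = EEGSNet(micro_config(seed=5)).forward(batch, training=False)
    np.testing.assert_array_equal(a.data, b.data)


def test_wrong_sequence_length_rejected(micro_model):
    with pytest.raises(ValueError, match="sequence length"):
        micro_model.forward(rng.random((1, 7, 76, 60, 3)), training=False)


def test_no_lstm_variant_is_permutation_equivariant(batch):
    """EEGSNet_0 predicts each epoch independently of its neighbours."""
    model = EEGSNet(micro_config(lstm_layers=0))
    probs, _ = model.forward(batch, training=False)
    perm = rng.permutation(10)
    shuffled = batch[:, perm]
    probs_perm, _ = model.forward(shuffled, training=False)
    for b in range(2):
        np.testing.assert_allclose(
            probs.data.reshape(2, 10, 5)[b, perm],
            probs_perm.data.reshape(2, 10, 5)[b],
            atol=1e-6,
        )


def test_full_model_uses_sequence_context(batch):
    """With an LSTM, a neighbouring epoch changes the current prediction."""
    model = EEGSNet(micro_config())
    probs, _ = model.forward(batch, training=False)
    modified = batch.copy()
    modified[:, 0] = 1.0 - modified[:, 0]
    probs2, _ = model.forward(modified, training=False)
    # predictions for untouched epochs 1..9 move
    assert np.abs(probs.data.reshape(2, 10, 5)[:, 1:] -
                  probs2.data.reshape(2, 10, 5)[:, 1:]).max() > 1e-8


def test_aux_head_uniform_for_zero_feature():
    head = Linear(16, 5, np.random.default_rng(0))
    head.weight.data[:] = 0.0
    probs = head(Tensor(np.zeros((1, 16)))).softmax()
    np.testing.assert_allclose(probs.data, 0.2, atol=1e-12)


# --- loss ------------------------------------------------------------------

def test_loss_uniform_predictions_closed_form():
    n = 8
    y = np.eye(5)[rng.integers(0, 5, n)]
    uni = Tensor(np.full((n, 5), 0.2))
    lc = compute_loss(uni, uni, y, aux_weight=0.5)
    assert lc.loss_total == pytest.approx(1.5 * np.log(5), abs=1e-9)


def test_loss_perfect_predictions_is_zero():
    y = np.eye(5)[[0, 3, 4]]
    perfect = Tensor(y.astype(np.float64))
    lc = compute_loss(perfect, perfect, y, aux_weight=0.5)
    assert lc.loss_total == pytest.approx(0.0, abs=1e-9)


def test_loss_hand_evaluated_two_sample_case():
    """main true-class probs (0.5, 0.25), aux (1, 1): total = (ln2+ln4)/2."""
    y = np.eye(5)[[1, 2]]
    main = np.array(
        [
            [0.125, 0.5, 0.125, 0.125, 0.125],
            [0.1875, 0.1875, 0.25, 0.1875, 0.1875],
        ]
    )
    lc = compute_loss(Tensor(main), Tensor(y.astype(float)), y)
    assert lc.loss_main == pytest.approx((np.log(2) + np.log(4)) / 2, abs=1e-9)
    assert lc.loss_aux == pytest.approx(0.0, abs=1e-9)
    assert lc.loss_total == pytest.approx(1.0397207708399179, abs=1e-6)


def test_loss_total_identity_and_shape_validation():
    y = np.eye(5)[[0, 1]]
    p = Tensor(np.full((2, 5), 0.2))
    lc = compute_loss(p, p, y, aux_weight=0.3)
    assert lc.loss_total == pytest.approx(lc.loss_main + 0.3 * lc.loss_aux, abs=1e-9)
    with pytest.raises(ValueError, match="match"):
        compute_loss(Tensor(np.full((3, 5), 0.2)), None, y)


# --- training step ---------------------------------------------------------

def test_gradient_reaches_every_parameter():
    model = EEGSNet(micro_config())
    imgs = rng.random((1, 10, 76, 60, 3)).astype(np.float32)
    y = np.eye(5)[rng.integers(0, 5, 10)]
    probs, aux = model.forward(imgs, training=True)
    lc = compute_loss(probs, aux, y)
    lc.tensor.backward()
    for i, p in enumerate(model.parameters()):
        assert p.grad is not None and np.abs(p.grad).sum() > 0, f"dead parameter {i}"


def test_single_training_step_decreases_loss():
    """A small step on one batch lowers the composite loss (dropout off)."""
    cfg = micro_config(seed=3)
    cfg.dropout_keep = 1.0  # deterministic training-mode forward
    model = EEGSNet(cfg)
    imgs = rng.random((2, 10, 76, 60, 3)).astype(np.float32)
    y = np.eye(5)[rng.integers(0, 5, 20)]
    params = model.parameters()
    opt = Adam(params, lr=1e-4)

    def training_loss():
        probs, aux = model.forward(imgs, training=True)
        return compute_loss(probs, aux, y)

    before = training_loss()
    opt.zero_grad()
    before.tensor.backward()
    clip_grad_norm(params, 5.0)
    opt.step()
    after = training_loss()
    assert after.loss_total < before.loss_total


def test_checkpoint_round_trip(tmp_path, batch):
    model = EEGSNet(micro_config(seed=9))
    path = tmp_path / "ckpt.npz"
    model.save(path)
    back = EEGSNet.load(path)
    a, _ = model.forward(batch, training=False)
    b, _ = back.forward(batch, training=False)
    np.testing.assert_array_equal(a.data, b.data)
    assert back.cfg == model.cfg
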