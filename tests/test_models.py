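import numpy as np
import pytest

from planttf.models import (
    ClassifierSpec,
    TrainConfig,
    TrainedModel,
    predict_proba,
    train_binary,
    train_stacker,
)

FAST = TrainConfig(
    max_epochs=30, min_updates=300, patience_updates=100, input_noise=0.2, seed=0
)


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(5)
    n = 120
    X = rng.normal(size=(n, 10))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    return X, y


def test_spec_rejects_non_decreasing_hidden():
    with pytest.raises(ValueError, match="decreasing"):
        ClassifierSpec(input_dim=4, hidden=(32, 64))


def test_spec_sigmoid_implies_single_output():
    with pytest.raises(ValueError):
        ClassifierSpec(input_dim=4, output_dim=3, output="sigmoid")


def test_binary_training_learns_separable_toy(separable_data):
    X, y = separable_data
    spec = ClassifierSpec(input_dim=10, hidden=(16, 8), dropout=0.1)
    model = train_binary(X, y, spec=spec, config=FAST)
    p = predict_proba(model, X)
    assert ((p > 0.5) == y).mean() >= 0.9
    assert np.all((p >= 0) & (p <= 1))


def test_training_loss_decreases_initially(separable_data):
    X, y = separable_data
    spec = ClassifierSpec(input_dim=10, hidden=(16, 8), dropout=0.0)
    cfg = TrainConfig(max_epochs=5, min_updates=1, patience_updates=1,
                      input_noise=0.0, seed=3)
    model = train_binary(X, y, spec=spec, config=cfg)
    losses = [h["train_loss"] for h in model.training_meta["history"]]
    assert losses[-1] < losses[0]


def test_single_class_labels_rejected():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError, match="single class"):
        train_binary(X, [1] * 10, config=FAST)


def test_retraining_same_seed_identical_weights(separable_data):
    X, y = separable_data
    spec = ClassifierSpec(input_dim=10, hidden=(8, 4), dropout=0.5)
    m1 = train_binary(X, y, spec=spec, config=FAST)
    m2 = train_binary(X, y, spec=spec, config=FAST)
    for w1, w2 in zip(m1.net.weights, m2.net.weights):
        assert np.array_equal(w1, w2)


def test_prediction_deterministic_dropout_off(separable_data):
    X, y = separable_data
    model = train_binary(
        X, y, spec=ClassifierSpec(input_dim=10, hidden=(8, 4)), config=FAST
    )
    p1 = predict_proba(model, X)
    p2 = predict_proba(model, X)
    assert np.array_equal(p1, p2)


def test_zero_input_gives_valid_probability(separable_data):
    X, y = separable_data
    model = train_binary(
        X, y, spec=ClassifierSpec(input_dim=10, hidden=(8, 4)), config=FAST
    )
    p = predict_proba(model, np.zeros((1, 10)))
    assert 0.0 <= p[0] <= 1.0


def test_dimension_mismatch_errors(separable_data):
    X, y = separable_data
    model = train_binary(
        X, y, spec=ClassifierSpec(input_dim=10, hidden=(8, 4)), config=FAST
    )
    with pytest.raises(ValueError, match="columns"):
        predict_proba(model, np.zeros((2, 7)))


def test_dropout_changes_training_but_not_inference(separable_data):
    X, y = separable_data
    m_dropout = train_binary(
        X, y, spec=ClassifierSpec(input_dim=10, hidden=(8, 4), dropout=0.5),
        config=FAST,
    )
    m_plain = train_binary(
        X, y, spec=ClassifierSpec(input_dim=10, hidden=(8, 4), dropout=0.0),
        config=FAST,
    )
    assert not np.array_equal(m_dropout.net.weights[0], m_plain.net.weights[0])


def test_save_load_roundtrip_bitwise(tmp_path, separable_data):
    X, y = separable_data
    model = train_binary(
        X, y, spec=ClassifierSpec(input_dim=10, hidden=(8, 4)), config=FAST
    )
    model.save(tmp_path / "model")
    back = TrainedModel.load(tmp_path / "model")
    assert back.spec == model.spec
    assert np.array_equal(predict_proba(back, X), predict_proba(model, X))


def test_stacker_output_normalized(rng):
    n, k = 90, 5
    labels_idx = rng.integers(0, k, size=n)
    P = rng.random((n, k)) * 0.1
    P[np.arange(n), labels_idx] = 0.9
    families = [f"F{i}" for i in range(k)]
    labels = [families[i] for i in labels_idx]
    model = train_stacker(P, labels, families, config=FAST)
    S = predict_proba(model, P)
    assert S.shape == (n, k)
    assert np.all(S >= 0)
    assert np.allclose(S.sum(axis=1), 1.0)
    assert model.spec.input_dim == k and model.spec.output_dim == k


def test_stacker_agrees_with_max_vote_on_clean_inputs(rng):
    n, k = 200, 6
    labels_idx = rng.integers(0, k, size=n)
    P = rng.random((n, k)) * 0.05
    P[np.arange(n), labels_idx] = 0.95
    families = [f"F{i}" for i in range(k)]
    model = train_stacker(
        P, [families[i] for i in labels_idx], families,
        config=TrainConfig(max_epochs=60, min_updates=600, patience_updates=200,
                           input_noise=0.05, seed=1),
    )
    S = predict_proba(model, P)
    agreement = (S.argmax(axis=1) == P.argmax(axis=1)).mean()
    assert agreement >= 0.95


def test_stacker_rejects_mismatched_columns(rng):
    P = rng.random((10, 3))
    with pytest.raises(ValueError, match="columns"):
        train_stacker(P, ["A"] * 10, ["A", "B"], config=FAST)
    with pytest.raises(ValueError, match="family order"):
        train_stacker(P, ["Z"] * 10, ["A", "B", "C"], config=FAST)


def test_nan_inputs_abort_with_diagnostic():
    X = np.full((20, 4), np.nan)
    y = [0, 1] * 10
    with pytest.raises(RuntimeError, match="non-finite"):
        train_binary(
            X, y, spec=ClassifierSpec(input_dim=4, hidden=(8, 4)), config=FAST
        )
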