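"""Confusion/metrics arithmetic, folding, transitions and the training loop."""

import numpy as np
import pytest

from eegsnet.reference import REFERENCE_CONFUSIONS
from eegsnet.signal_io import Stage
from eegsnet.training_eval import (
    ConfusionMatrix,
    TrainConfig,
    build_eval_sequences,
    build_train_sequences,
    confusion,
    count_transitions,
    make_folds,
    metrics,
    train_fold,
)
from .test_model import micro_config


# --- confusion -------------------------------------------------------------

def test_confusion_enumeration():
    cm = confusion(["W", "W", "N1"], ["W", "N1", "N1"])
    expect = np.zeros((5, 5), dtype=int)
    expect[0, 0] = 1
    expect[0, 1] = 1
    expect[1, 1] = 1
    np.testing.assert_array_equal(cm.counts, expect)


def test_confusion_identical_sequences_diagonal():
    labs = [0, 1, 2, 3, 4, 2, 2]
    cm = confusion(labs, labs)
    assert (cm.counts - np.diag(np.diag(cm.counts)) == 0).all()
    assert cm.total == 7


def test_confusion_empty_input():
    cm = confusion([], [])
    assert cm.total == 0
    with pytest.raises(ValueError):
        metrics(cm)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError, match="lengths differ"):
        confusion([0, 1], [0])


# --- metrics ---------------------------------------------------------------

def test_benchmark_matrix_edfx8_headline_numbers():
    r = metrics(ConfusionMatrix(REFERENCE_CONFUSIONS["sleep-edfx-8"]))
    assert round(r.acc, 2) == 94.17
    assert round(r.precision[1], 1) == 76.5
    assert round(r.recall[1], 1) == 64.8
    assert round(r.f1[1], 2) == 70.16
    assert round(r.kappa, 2) == 0.91
    assert round(r.mf1, 2) == 87.78


def test_benchmark_matrix_edfx20_headline_numbers():
    r = metrics(ConfusionMatrix(REFERENCE_CONFUSIONS["sleep-edfx-20"]))
    assert round(r.acc, 2) == 86.82
    assert round(r.mf1, 2) == 81.57
    assert round(r.kappa, 2) == 0.82


@pytest.mark.parametrize(
    "name,printed_mf1",
    [("sleep-edfx-8", 87.78), ("sleep-edfx-20", 81.57), ("shhs", 78.54)],
)
def test_macro_f1_from_unrounded_f1s(name, printed_mf1):
    r = metrics(ConfusionMatrix(REFERENCE_CONFUSIONS[name]))
    assert round(r.mf1, 2) == printed_mf1


def test_perfect_diagonal_metrics():
    r = metrics(ConfusionMatrix(np.diag([5, 4, 3, 2, 1])))
    assert r.acc == 100.0 and r.mf1 == 100.0 and r.kappa == 1.0


def test_metrics_agree_with_sklearn_oracle():
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(12)
    for _ in range(100):
        counts = rng.integers(0, 25, size=(5, 5))
        if counts.sum() == 0:
            counts[0, 0] = 1
        ref, pred = [], []
        for i in range(5):
            for j in range(5):
                ref += [i] * counts[i, j]
                pred += [j] * counts[i, j]
        r = metrics(ConfusionMatrix(counts))
        pr, re, f1, _ = sklearn.precision_recall_fscore_support(
            ref, pred, labels=range(5), zero_division=0
        )
        np.testing.assert_allclose(r.precision, 100 * pr, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(r.recall, 100 * re, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(r.f1, 100 * f1, rtol=1e-10, atol=1e-10)
        assert r.acc == pytest.approx(
            100 * sklearn.accuracy_score(ref, pred), rel=1e-10
        )
        if len(set(ref)) > 1 or len(set(pred)) > 1:
            assert r.kappa == pytest.approx(
                sklearn.cohen_kappa_score(ref, pred, labels=list(range(5))), rel=1e-8, abs=1e-10
            )


def test_kappa_bounded_and_one_only_for_diagonal():
    rng = np.random.default_rng(3)
    for _ in range(50):
        counts = rng.integers(0, 30, size=(5, 5))
        if counts.sum() == 0:
            continue
        r = metrics(ConfusionMatrix(counts))
        assert r.kappa <= 1.0 + 1e-12
        off_diag = counts.sum() - np.trace(counts)
        if r.kappa == 1.0:
            assert off_diag == 0 and np.trace(counts) > 0


def test_zero_margin_class_warns_and_reports_zero():
    counts = np.diag([10, 0, 10, 10, 10])
    with pytest.warns(UserWarning, match="empty margin"):
        r = metrics(ConfusionMatrix(counts))
    assert r.f1[1] == 0.0


# --- folding ---------------------------------------------------------------

def test_loso_with_twenty_subjects():
    ds = {f"s{i}": 100 for i in range(20)}
    spec = make_folds(ds, "subject_wise", k=20, seed=0)
    sizes = [len(spec.test_keys(f)) for f in range(20)]
    assert sizes == [1] * 20
    assert set(spec.assignment) == set(ds)


def test_subject_wise_partition_with_forty_subjects():
    ds = {f"s{i}": 50 for i in range(40)}
    spec = make_folds(ds, "subject_wise", k=20, seed=1)
    sizes = [len(spec.test_keys(f)) for f in range(20)]
    assert sizes == [2] * 20
    assert sorted(sum((spec.test_keys(f) for f in range(20)), [])) == sorted(ds)


def test_subject_wise_too_few_subjects_suggests_loso():
    with pytest.raises(ValueError, match="leave-one-subject-out"):
        make_folds({f"s{i}": 10 for i in range(8)}, "subject_wise", k=20)


def test_epoch_wise_blocks_conserved():
    ds = {f"s{i}": 100 for i in range(10)}  # 10 blocks each, 100 total
    spec = make_folds(ds, "epoch_wise", k=20, seed=2)
    all_blocks = sum((spec.test_keys(f) for f in range(20)), [])
    assert len(all_blocks) == 100 and len(set(all_blocks)) == 100
    assert {len(spec.test_keys(f)) for f in range(20)} == {5}


# --- transitions -----------------------------------------------------------

def test_transition_enumeration():
    pairs = [("W", "N1"), ("W", "REM"), ("N1", "N2"), ("REM", "N2")]
    out = count_transitions(["W", "W", "N1", "N2", "N2", "REM"], pairs)
    assert [out[(Stage[a], Stage[b])] for a, b in pairs] == [1, 0, 1, 0]


def test_transition_constant_hypnogram_zero():
    out = count_transitions(["N2"] * 100, [("N1", "N2"), ("N2", "N3")])
    assert all(v == 0 for v in out.values())


def test_transitions_not_counted_across_subjects():
    seqs = [["N2", "W"], ["N1", "N2"]]
    out = count_transitions(seqs, [("W", "N1"), ("N1", "N2")])
    assert out[(Stage.W, Stage.N1)] == 0  # boundary W->N1 ignored
    assert out[(Stage.N1, Stage.N2)] == 1


def test_transition_unknown_stage_rejected():
    with pytest.raises(ValueError, match="unknown stage"):
        count_transitions(["W", "N1"], [("W", "XX")])


# --- sequence assembly -----------------------------------------------------

def _fake_subject(n, seed=0):
    rng = np.random.default_rng(seed)
    return (
        rng.random((n, 76, 60, 3)).astype(np.float32),
        rng.integers(0, 5, n).astype(np.int64),
    )


def test_train_sequences_drop_remainder():
    data = {"a": _fake_subject(25), "b": _fake_subject(10, 1)}
    seqs, labs = build_train_sequences(data, 10)
    assert seqs.shape == (3, 10, 76, 60, 3)


def test_eval_sequences_score_every_epoch_once():
    data = {"a": _fake_subject(27), "b": _fake_subject(10, 1)}
    seqs, labs, masks = build_eval_sequences(data, 10)
    assert masks.sum() == 37  # 27 + 10, tail epochs counted exactly once
    assert seqs.shape[0] == 4  # 2 full + 1 tail for "a", 1 full for "b"


# --- training loop ---------------------------------------------------------

@pytest.fixture(scope="module")
def toy_split(tiny_dataset):
    ids = sorted(tiny_dataset)
    train = {k: tiny_dataset[k] for k in ids[:4]}
    test = {k: tiny_dataset[k] for k in ids[4:]}
    return train, test


def test_train_fold_validates_splits(toy_split):
    train, test = toy_split
    with pytest.raises(ValueError, match="overlap"):
        train_fold(train, train, TrainConfig(iterations_per_fold=1), micro_config())
    with pytest.raises(ValueError, match="nonempty"):
        train_fold(train, {}, TrainConfig(iterations_per_fold=1), micro_config())


def test_train_fold_best_tracking_and_determinism(toy_split):
    train, test = toy_split
    cfg = TrainConfig(
        iterations_per_fold=3, eval_every=1, learning_rate=1e-3, seed=4
    )
    log1, log2 = [], []
    _, best1 = train_fold(train, test, cfg, micro_config(seed=4), log=log1)
    _, best2 = train_fold(train, test, cfg, micro_config(seed=4), log=log2)
    accs = [e["test_acc"] for e in log1 if "test_acc" in e]
    assert best1.acc == max(accs)  # best-so-far tracking is monotone
    assert best1.acc == best2.acc and best1.mf1 == best2.mf1  # seeded determinism
    assert [e for e in log1 if "test_acc" in e] == [e for e in log2 if "test_acc" in e]
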