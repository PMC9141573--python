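"""Cross-validation protocol, training loop, and the evaluation suite.

The protocol: data are split into 20 folds — subject-wise where there are
enough subjects (every subject's epochs stay in one fold; with exactly 20
subjects this is leave-one-subject-out), epoch-wise otherwise (contiguous
10-epoch sequence blocks are assigned to folds so sequence integrity is
preserved).  Each fold trains for a fixed number of passes over its training
sequences in batches of 5 sequences, evaluates on the held-out fold every 3
passes with the auxiliary head removed and dropout disabled, and keeps the
best test report (highest accuracy, ties broken by macro-F1).

Evaluation: 5×5 confusion matrices (rows = reference, columns = predicted, in
W/N1/N2/N3/REM order) and the derived per-class precision/recall/F1, overall
accuracy, macro-F1 and Cohen's kappa — plus hypnogram transition counting,
the statistic that motivates sequence learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import EEGSNet, ModelConfig, compute_loss
from .nn import Adam, clip_grad_norm
from .signal_io import STAGE_ORDER, Stage

__all__ = [
    "FoldSpec",
    "TrainConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "SubjectData",
    "make_folds",
    "build_train_sequences",
    "build_eval_sequences",
    "evaluate_model",
    "train_fold",
    "cross_validate",
    "confusion",
    "metrics",
    "count_transitions",
]

N_CLASSES = 5
_STAGE_NAMES = [s.name for s in STAGE_ORDER]

#: (images (n, 76, 60, 3), integer labels (n,)) for one subject.
SubjectData = tuple[np.ndarray, np.ndarray]


@dataclass
class FoldSpec:
    """A k-fold partition, keyed by subject or by (subject, block) pair."""

    mode: str  # "subject_wise" | "epoch_wise"
    k: int
    assignment: dict  # subject -> fold, or (subject, block_index) -> fold

    def test_keys(self, fold: int) -> list:
        return [key for key, f in self.assignment.items() if f == fold]

    def train_keys(self, fold: int) -> list:
        return [key for key, f in self.assignment.items() if f != fold]


@dataclass
class TrainConfig:
    """Training protocol parameters (defaults follow the published protocol)."""

    batch_sequences: int = 5
    seq_len: int = 10
    iterations_per_fold: int = 150
    eval_every: int = 3
    aux_weight: float = 0.5
    learning_rate: float = 1e-4
    grad_clip: float = 5.0
    bn_recal_batches: int = 8  # batch-norm re-estimation before each evaluation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_sequences", "seq_len", "iterations_per_fold", "eval_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConfusionMatrix:
    """5×5 counts; rows = reference stage, columns = predicted stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected 5×5 counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class PR/RE/F1 (percent), overall ACC/MF1 (percent) and kappa."""

    precision: np.ndarray  # percent, per class in W/N1/N2/N3/REM order
    recall: np.ndarray
    f1: np.ndarray
    acc: float
    mf1: float
    kappa: float
    n: int
    cm: "ConfusionMatrix | None" = None

    def to_dict(self) -> dict:
        per_class = {
            name: {
                "PR": round(float(self.precision[i]), 2),
                "RE": round(float(self.recall[i]), 2),
                "F1": round(float(self.f1[i]), 2),
            }
            for i, name in enumerate(_STAGE_NAMES)
        }
        return {
            "ACC": round(self.acc, 2),
            "MF1": round(self.mf1, 2),
            "kappa": round(self.kappa, 2),
            "n": self.n,
            "per_class": per_class,
        }


def confusion(reference, predicted) -> ConfusionMatrix:
    """Count reference-vs-predicted stage pairs.

    Accepts integer class indices or :class:`Stage` members; empty input
    yields an all-zero matrix.
    """
    ref = _as_indices(reference)
    pred = _as_indices(predicted)
    if len(ref) != len(pred):
        raise ValueError(
            f"reference ({len(ref)}) and predicted ({len(pred)}) lengths differ"
        )
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (ref, pred), 1)
    return ConfusionMatrix(counts)


def _as_indices(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, Stage):
            out.append(lab.value)
        elif isinstance(lab, str):
            out.append(Stage[lab].value)
        else:
            v = int(lab)
            if not 0 <= v < N_CLASSES:
                raise ValueError(f"label index {v} outside [0, {N_CLASSES})")
            out.append(v)
    return np.asarray(out, dtype=np.int64)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive PR/RE/F1/ACC/MF1/kappa from a confusion matrix.

    PR_k = TP_k / column-sum, RE_k = TP_k / row-sum, F1_k harmonic mean,
    ACC = 100·trace/total, MF1 = unweighted mean of the unrounded per-class
    F1s, kappa = (p_o − p_e)/(1 − p_e) with p_e from the marginal products.
    Zero denominators yield 0 for the affected entries, with a warning.
    """
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total == 0:
        raise ValueError("cannot compute metrics of an empty confusion matrix")
    tp = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    pr = np.zeros(N_CLASSES)
    re = np.zeros(N_CLASSES)
    f1 = np.zeros(N_CLASSES)
    for k in range(N_CLASSES):
        if col[k] == 0 or row[k] == 0 or tp[k] == 0:
            if col[k] == 0 or row[k] == 0:
                warnings.warn(
                    f"class {_STAGE_NAMES[k]} has an empty margin; "
                    "its PR/RE/F1 are reported as 0",
                    stacklevel=2,
                )
            pr[k] = tp[k] / col[k] if col[k] > 0 else 0.0
            re[k] = tp[k] / row[k] if row[k] > 0 else 0.0
            f1[k] = 0.0
        else:
            pr[k] = tp[k] / col[k]
            re[k] = tp[k] / row[k]
            f1[k] = 2 * pr[k] * re[k] / (pr[k] + re[k])
    p_o = tp.sum() / total
    p_e = float((row * col).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return MetricsReport(
        precision=100 * pr,
        recall=100 * re,
        f1=100 * f1,
        acc=float(100 * p_o),
        mf1=float(100 * f1.mean()),
        kappa=float(kappa),
        n=int(total),
    )


def count_transitions(hypnogram, pairs) -> dict[tuple, int]:
    """Count adjacent ordered stage pairs in one or several hypnograms.

    ``hypnogram`` is a single stage sequence or a list of per-subject
    sequences; adjacency is never counted across subjects.  ``pairs`` is a
    list of (from, to) stages (members or names).  Returns counts per pair.
    """
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    if isinstance(hypnogram[0], (list, tuple, np.ndarray)):
        sequences = hypnogram
    else:
        sequences = [hypnogram]

    def stage_of(x) -> Stage:
        if isinstance(x, Stage):
            return x
        if isinstance(x, str):
            try:
                return Stage[x]
            except KeyError:
                raise ValueError(f"unknown stage {x!r}") from None
        return Stage(int(x))

    want = [(stage_of(a), stage_of(b)) for a, b in pairs]
    out = {p: 0 for p in want}
    for seq in sequences:
        states = [stage_of(s) for s in seq]
        for a, b in zip(states[:-1], states[1:]):
            if (a, b) in out:
                out[(a, b)] += 1
    return out


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

def make_folds(
    dataset: dict[str, int],
    mode: str,
    k: int = 20,
    seed: int = 0,
    seq_len: int = 10,
) -> FoldSpec:
    """Partition a dataset (subject → epoch count) into ``k`` folds.

    ``subject_wise``: subjects are shuffled with the seed and dealt
    round-robin so every subject's epochs share one fold; with exactly ``k``
    subjects this is leave-one-subject-out.  ``epoch_wise``: contiguous
    ``seq_len``-epoch blocks (not single epochs) are shuffled and dealt,
    preserving sequence integrity.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    if mode == "subject_wise":
        subjects = sorted(dataset)
        if len(subjects) < k:
            raise ValueError(
                f"subject_wise folding needs at least {k} subjects, got "
                f"{len(subjects)}; consider leave-one-subject-out with "
                f"k={len(subjects)}"
            )
        order = list(rng.permutation(subjects))
        return FoldSpec(
            mode=mode, k=k, assignment={s: i % k for i, s in enumerate(order)}
        )
    if mode == "epoch_wise":
        # full blocks only; a trailing remainder travels with its subject's
        # last full block so every epoch stays scoreable
        blocks = [
            (subj, b)
            for subj in sorted(dataset)
            for b in range(max(1, dataset[subj] // seq_len))
        ]
        order = rng.permutation(len(blocks))
        return FoldSpec(
            mode=mode,
            k=k,
            assignment={blocks[j]: i % k for i, j in enumerate(order)},
        )
    raise ValueError(f"unknown folding mode {mode!r}")


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------

def build_train_sequences(
    data: dict[str, SubjectData], seq_len: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping ``seq_len``-epoch training sequences in natural order.

    A trailing remainder shorter than ``seq_len`` is dropped (training only).
    Returns (sequences (S, seq_len, 76, 60, 3), labels (S, seq_len)).
    """
    seqs, labs = [], []
    for subj in sorted(data):
        images, labels = data[subj]
        n = len(labels) // seq_len * seq_len
        for s in range(0, n, seq_len):
            seqs.append(images[s : s + seq_len])
            labs.append(labels[s : s + seq_len])
    if not seqs:
        raise ValueError(f"no complete {seq_len}-epoch sequence in training data")
    return np.stack(seqs), np.stack(labs)


def build_eval_sequences(
    data: dict[str, SubjectData], seq_len: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluation sequences covering every epoch exactly once.

    Full blocks are scored as-is; a trailing remainder is scored through one
    extra tail-aligned sequence whose already-scored epochs are masked out.
    Returns (sequences, labels, count_mask) with mask True where the epoch is
    scored.
    """
    seqs, labs, masks = [], [], []
    for subj in sorted(data):
        images, labels = data[subj]
        n = len(labels)
        if n < seq_len:
            warnings.warn(
                f"subject {subj} has only {n} epochs (<{seq_len}); skipped",
                stacklevel=2,
            )
            continue
        full = n // seq_len
        for s in range(full):
            seqs.append(images[s * seq_len : (s + 1) * seq_len])
            labs.append(labels[s * seq_len : (s + 1) * seq_len])
            masks.append(np.ones(seq_len, dtype=bool))
        rem = n - full * seq_len
        if rem:
            seqs.append(images[n - seq_len : n])
            labs.append(labels[n - seq_len : n])
            m = np.zeros(seq_len, dtype=bool)
            m[-rem:] = True
            masks.append(m)
    if not seqs:
        raise ValueError("no evaluable sequence in data")
    return np.stack(seqs), np.stack(labs), np.stack(masks)


def evaluate_model(
    model: EEGSNet, data: dict[str, SubjectData], batch: int = 10
) -> MetricsReport:
    """Score held-out data: deterministic forward pass, no auxiliary head."""
    seqs, labs, masks = build_eval_sequences(data, model.cfg.seq_len)
    t = model.cfg.seq_len
    refs, preds = [], []
    for s in range(0, len(seqs), batch):
        chunk = seqs[s : s + batch]
        pred = model.predict(chunk).reshape(len(chunk), t)
        m = masks[s : s + batch]
        refs.append(labs[s : s + batch][m])
        preds.append(pred[m])
    cm = confusion(np.concatenate(refs), np.concatenate(preds))
    report = metrics(cm)
    report.cm = cm
    return report


def train_fold(
    train_data: dict[str, SubjectData],
    test_data: dict[str, SubjectData],
    cfg: TrainConfig | None = None,
    mcfg: ModelConfig | None = None,
    log: list | None = None,
) -> tuple[EEGSNet, MetricsReport]:
    """Train on one fold's training split, track the best held-out report.

    Runs ``iterations_per_fold`` passes over the training sequences in
    batches of ``batch_sequences`` sequences, evaluating on the test split
    every ``eval_every`` passes (auxiliary classifier removed, dropout
    disabled).  Best report = highest ACC, ties broken by MF1.
    """
    cfg = cfg or TrainConfig()
    mcfg = mcfg or ModelConfig()
    if not train_data or not test_data:
        raise ValueError("train and test splits must both be nonempty")
    if set(train_data) & set(test_data):
        raise ValueError("train and test subjects overlap")
    seqs, labs = build_train_sequences(train_data, cfg.seq_len)
    model = EEGSNet(mcfg)
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    eye = np.eye(N_CLASSES)

    best: MetricsReport | None = None
    for p in range(1, cfg.iterations_per_fold + 1):
        order = rng.permutation(len(seqs))
        for s in range(0, len(order), cfg.batch_sequences):
            idx = order[s : s + cfg.batch_sequences]
            main, aux = model.forward(seqs[idx], training=True)
            y = eye[labs[idx].reshape(-1)]
            loss = compute_loss(main, aux, y, cfg.aux_weight)
            opt.zero_grad()
            loss.tensor.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
            if log is not None:
                log.append({"pass": p, "loss": loss.loss_total})
        if p % cfg.eval_every == 0 or p == cfg.iterations_per_fold:
            if cfg.bn_recal_batches > 0:
                _recalibrate(model, seqs, cfg)
            report = evaluate_model(model, test_data)
            if (
                best is None
                or report.acc > best.acc
                or (report.acc == best.acc and report.mf1 > best.mf1)
            ):
                best = report
            if log is not None:
                log.append({"pass": p, "test_acc": report.acc, "test_mf1": report.mf1})
    assert best is not None
    return model, best


def _recalibrate(model: EEGSNet, seqs: np.ndarray, cfg: TrainConfig) -> None:
    """Re-estimate batch-norm statistics on evenly spaced training batches.

    The training loop takes few optimiser steps compared with GPU-scale runs,
    so the momentum-averaged statistics lag the weights; re-estimating them
    under the current weights makes each periodic evaluation reflect the
    model actually being scored.
    """
    t = cfg.seq_len
    groups = max(1, min(cfg.bn_recal_batches, len(seqs) // cfg.batch_sequences))
    picks = np.linspace(0, len(seqs) - cfg.batch_sequences, groups).astype(int)
    batches = [
        seqs[i : i + cfg.batch_sequences].reshape(-1, 76, 60, 3) for i in picks
    ]
    model.recalibrate_batchnorm(batches)


def cross_validate(
    data: dict[str, SubjectData],
    mode: str = "subject_wise",
    k: int = 20,
    cfg: TrainConfig | None = None,
    mcfg: ModelConfig | None = None,
) -> tuple[ConfusionMatrix, list[MetricsReport]]:
    """Full k-fold protocol; combines each fold's test predictions.

    Each fold's final model scores its own held-out split once; the scored
    epochs of all folds partition the dataset, and the pooled confusion
    matrix yields the overall metrics.
    """
    cfg = cfg or TrainConfig()
    folds = make_folds(
        {s: len(v[1]) for s, v in data.items()}, mode, k, cfg.seed, cfg.seq_len
    )
    pooled = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    reports = []
    for fold in range(k):
        if mode == "subject_wise":
            test = {s: data[s] for s in folds.test_keys(fold)}
            train = {s: data[s] for s in folds.train_keys(fold)}
        else:
            test = _slice_blocks(data, folds.test_keys(fold), cfg.seq_len)
            train = _slice_blocks(data, folds.train_keys(fold), cfg.seq_len)
        if not test:
            continue
        _, report = train_fold(train, test, cfg, mcfg)
        reports.append(report)
        pooled += report.cm.counts
    return ConfusionMatrix(pooled), reports


def _slice_blocks(
    data: dict[str, SubjectData], keys: list, seq_len: int
) -> dict[str, SubjectData]:
    """Materialise (subject, block) fold keys as pseudo-subject splits.

    The last block of each subject absorbs the trailing remainder.
    """
    out: dict[str, SubjectData] = {}
    for subj, block in keys:
        images, labels = data[subj]
        n_blocks = max(1, len(labels) // seq_len)
        lo = block * seq_len
        hi = (block + 1) * seq_len if block < n_blocks - 1 else len(labels)
        out[f"{subj}#b{block}"] = (images[lo:hi], labels[lo:hi])
    return out
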