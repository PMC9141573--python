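"""The EEGSNet network.

Architecture: a five-block residual CNN turns each 76×60×3 spectrogram image
into a 64-d feature vector (3×3 convolutions with exact-erf GELU, 2×2 max
pooling, batch normalisation, dropout; skip additions pair blocks 1→2 and
3→4; block 5 adds a 3×3 stride-1 average pooling; global average pooling
yields the feature).  A two-layer bidirectional LSTM (128 hidden units per
direction) reads sequences of 10 consecutive epoch features and a dense
softmax over the concatenated final-layer directions predicts the five AASM
stages per epoch.  An auxiliary softmax head on the raw CNN features is used
during training only, its cross-entropy added to the main loss with weight
0.5:

    Loss = Loss_main + 0.5 · Loss_aux

with Loss_main = −(1/N) Σᵢ Σₖ yₖ⁽ⁱ⁾ log p_main,ₖ⁽ⁱ⁾ and Loss_aux analogous.
Ablation variants keep the CNN and change only the recurrent depth
(0 = no LSTM, per-epoch softmax on the 64-d features; 1 or 3 layers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, gelu_array
from .nn import BatchNorm2d, BiLSTM, Conv3x3, Linear

__all__ = [
    "ModelConfig",
    "EEGSNet",
    "LossComponents",
    "gelu",
    "compute_loss",
    "count_parameters",
    "describe",
    "small_config",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    The defaults reproduce the published EEGSNet: channel widths
    (16, 16, 32, 32, 64) satisfy the stated first convolution Conv(16, 3×3, 1),
    the 64-d global-average-pooled feature, residual channel matching, and the
    ≈0.6 M trainable-parameter budget.  ``lstm_layers`` 0/1/3 give the
    ablation variants EEGSNet_0/1/3.
    """

    conv_channels: tuple[int, ...] = (16, 16, 32, 32, 64)
    convs_per_block: int = 1
    dropout_keep: float = 0.5
    lstm_layers: int = 2
    lstm_hidden: int = 128
    seq_len: int = 10
    n_classes: int = 5
    aux_weight: float = 0.5
    feature_dim: int = 64
    seed: int = 42

    def __post_init__(self) -> None:
        cc = tuple(self.conv_channels)
        if len(cc) != 5 or any(c <= 0 for c in cc):
            raise ValueError(f"conv_channels must be 5 positive ints, got {cc}")
        if cc[0] != cc[1] or cc[2] != cc[3]:
            raise ValueError(
                "residual additions require conv_channels[0]==conv_channels[1] "
                f"and conv_channels[2]==conv_channels[3]; got {cc}"
            )
        if cc[4] != self.feature_dim:
            raise ValueError(
                f"conv_channels[4] ({cc[4]}) must equal feature_dim "
                f"({self.feature_dim}): it is the global-average-pooled width"
            )
        if self.lstm_layers not in (0, 1, 2, 3):
            raise ValueError(f"lstm_layers must be in {{0,1,2,3}}, got {self.lstm_layers}")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError(f"dropout_keep must be in (0,1], got {self.dropout_keep}")
        self.conv_channels = cc


def small_config(seed: int = 42) -> ModelConfig:
    """A narrow EEGSNet for CPU-scale experiments on synthetic data.

    Same topology (5 residual conv blocks, 2-layer Bi-LSTM, auxiliary head),
    roughly a quarter of the compute of the default widths.
    """
    return ModelConfig(
        conv_channels=(8, 8, 16, 16, 32),
        lstm_hidden=64,
        feature_dim=32,
        seed=seed,
    )


def gelu(x):
    """Exact Gaussian error linear unit, x·Φ(x) with Φ the standard normal CDF."""
    return gelu_array(x)


@dataclass
class LossComponents:
    """The composite training loss and its parts."""

    loss_main: float
    loss_aux: float
    loss_total: float
    N: int
    C: int
    y: np.ndarray
    tensor: Tensor = field(repr=False, default=None)


class EEGSNet:
    """CNN feature extractor + Bi-LSTM sequence classifier + auxiliary head."""

    def __init__(self, cfg: ModelConfig | None = None):
        self.cfg = cfg or ModelConfig()
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0]
        )
        cc = cfg.conv_channels
        in_ch = 3
        self.convs: list[list[Conv3x3]] = []
        self.bns: list[BatchNorm2d] = []
        for ch in cc:
            block = []
            d = in_ch
            for _ in range(cfg.convs_per_block):
                block.append(Conv3x3(d, ch, rng))
                d = ch
            self.convs.append(block)
            self.bns.append(BatchNorm2d(ch))
            in_ch = ch
        self.aux_head = Linear(cfg.feature_dim, cfg.n_classes, rng)
        self.lstm = BiLSTM(cfg.feature_dim, cfg.lstm_hidden, cfg.lstm_layers, rng)
        self.main_head = Linear(self.lstm.out_dim, cfg.n_classes, rng)

    # -- parameter access -----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for block in self.convs:
            for conv in block:
                out += conv.parameters()
        for bn in self.bns:
            out += bn.parameters()
        out += self.aux_head.parameters()
        out += self.lstm.parameters()
        out += self.main_head.parameters()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward passes -------------------------------------------------------
    def _block(
        self,
        x: Tensor,
        i: int,
        mode: str,
        skip: Tensor | None,
        bn_momentum: float,
    ) -> Tensor:
        for conv in self.convs[i]:
            x = conv(x).gelu()
        if skip is not None:
            # residual add on the pre-pooling map, where shapes match
            x = x + skip
        x = x.maxpool2x2()
        if i == 4:
            x = x.avgpool3x3_same()
        x = self.bns[i](x, training=mode != "eval", momentum=bn_momentum)
        if mode == "train" and self.cfg.dropout_keep < 1.0:
            x = x.dropout(self.cfg.dropout_keep, self._dropout_rng)
        return x

    def features(
        self,
        images: np.ndarray,
        training: bool = False,
        _mode: str | None = None,
        _bn_momentum: float = 0.1,
    ) -> Tensor:
        """CNN feature extraction: (B, 76, 60, 3) images → (B, feature_dim).

        ``_mode`` distinguishes "train" (batch statistics, dropout),
        "eval" (running statistics, no dropout) and "stats" (batch
        statistics, no dropout — used only for batch-norm recalibration).
        """
        mode = _mode or ("train" if training else "eval")
        images = np.asarray(images)
        if images.ndim != 4 or images.shape[1:] != (76, 60, 3):
            raise ValueError(f"expected (B, 76, 60, 3) images, got {images.shape}")
        x = Tensor(np.moveaxis(images, -1, 1).astype(np.float32))
        out1 = self._block(x, 0, mode, None, _bn_momentum)
        out2 = self._block(out1, 1, mode, out1, _bn_momentum)
        out3 = self._block(out2, 2, mode, None, _bn_momentum)
        out4 = self._block(out3, 3, mode, out3, _bn_momentum)
        out5 = self._block(out4, 4, mode, None, _bn_momentum)
        return out5.mean(axis=(2, 3))  # global average pooling

    def recalibrate_batchnorm(self, image_batches) -> None:
        """Re-estimate batch-norm running statistics over the given batches.

        With few optimiser steps the momentum-averaged statistics lag the
        moving weights, and the lag compounds across the five blocks; this
        resets the buffers and replaces them with the plain average of the
        batch statistics under the current weights (dropout disabled), the
        distribution evaluation actually sees.
        """
        first = True
        for k, imgs in enumerate(image_batches, start=1):
            if first:
                for bn in self.bns:
                    bn.reset_stats()
                first = False
            # momentum 1/k turns the EMA into a cumulative average
            self.features(np.asarray(imgs), _mode="stats", _bn_momentum=1.0 / k)

    def forward(
        self, images: np.ndarray, training: bool = False
    ) -> tuple[Tensor, Tensor | None]:
        """Full forward pass over whole sequences.

        ``images``: (batch, seq_len, 76, 60, 3).  Returns per-epoch main-head
        probabilities of shape (batch·seq_len, n_classes) in sequence order,
        and auxiliary-head probabilities in training mode (``None`` in
        evaluation: the auxiliary classifier is removed at test time).
        """
        images = np.asarray(images)
        if images.ndim != 5 or images.shape[2:] != (76, 60, 3):
            raise ValueError(
                f"expected (batch, seq_len, 76, 60, 3) sequences, got {images.shape}"
            )
        b, t = images.shape[:2]
        if t != self.cfg.seq_len:
            raise ValueError(f"sequence length {t} != configured {self.cfg.seq_len}")
        feats = self.features(images.reshape(b * t, 76, 60, 3), training=training)
        aux = self.aux_head(feats).softmax() if training else None
        if self.cfg.lstm_layers == 0:
            main = self.main_head(feats).softmax()
            return main, aux
        per_step = [feats[[i * t + s for i in range(b)], :] for s in range(t)]
        outs = self.lstm(per_step)  # seq_len tensors of (b, 2·hidden)
        logits = [self.main_head(h) for h in outs]
        # back to (b·t, C) in natural order
        stacked = concat(
            [z.reshape(b, 1, self.cfg.n_classes) for z in logits], axis=1
        ).reshape(b * t, self.cfg.n_classes)
        return stacked.softmax(), aux

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Deterministic evaluation: per-epoch argmax labels, shape (batch·seq_len,)."""
        probs, _ = self.forward(images, training=False)
        return probs.data.argmax(axis=1)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save weights (NPZ) plus a JSON sidecar with the configuration."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self.bns):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.cfg), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EEGSNet":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        cfg = ModelConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads(sidecar.read_text()).items()
        })
        model = cls(cfg)
        with np.load(path) as z:
            for i, p in enumerate(model.parameters()):
                p.data = z[f"p{i}"]
            for i, bn in enumerate(model.bns):
                bn.running_mean = z[f"rm{i}"]
                bn.running_var = z[f"rv{i}"]
        return model


def compute_loss(
    main: Tensor,
    aux: Tensor | None,
    y: np.ndarray,
    aux_weight: float = 0.5,
) -> LossComponents:
    """Composite cross-entropy: Loss = Loss_main + aux_weight · Loss_aux.

    ``main``/``aux`` are probability tensors of shape (N, C); ``y`` is one-hot
    (N, C).  Probabilities are clamped to [1e−12, 1] inside the log.  ``aux``
    may be ``None`` (evaluation), in which case Loss_aux = 0.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 2:
        raise ValueError(f"y must be one-hot (N, C), got shape {y.shape}")
    n, c = y.shape
    if main.shape != (n, c):
        raise ValueError(f"main predictions {main.shape} do not match labels {(n, c)}")
    yt = Tensor(y.astype(main.data.dtype))
    loss_main = -(yt * main.log_clamped()).sum() * (1.0 / n)
    if aux is not None:
        if aux.shape != (n, c):
            raise ValueError(f"aux predictions {aux.shape} do not match labels {(n, c)}")
        loss_aux = -(yt * aux.log_clamped()).sum() * (1.0 / n)
        total = loss_main + aux_weight * loss_aux
    else:
        loss_aux = None
        total = loss_main
    return LossComponents(
        loss_main=float(loss_main.data),
        loss_aux=float(loss_aux.data) if loss_aux is not None else 0.0,
        loss_total=float(total.data),
        N=n,
        C=c,
        y=y,
        tensor=total,
    )


def count_parameters(cfg: ModelConfig | None = None) -> int:
    """Total trainable scalars of the configured network (both heads included)."""
    return EEGSNet(cfg or ModelConfig()).n_parameters()


def describe(cfg: ModelConfig | None = None) -> str:
    """Human-readable layer table with per-layer and total parameter counts."""
    cfg = cfg or ModelConfig()
    model = EEGSNet(cfg)
    lines = []
    total = 0

    def row(name: str, n: int) -> None:
        nonlocal total
        total += n
        lines.append(f"{name:<38s} {n:>10,d}")

    in_ch = 3
    for i, ch in enumerate(cfg.conv_channels, start=1):
        n_conv = sum(
            p.data.size for p in
            (q for conv in model.convs[i - 1] for q in conv.parameters())
        )
        row(f"block_{i}: Conv({ch},3x3,1)+GELU+pool+BN", n_conv + 2 * ch)
        in_ch = ch
    row("aux head: dense softmax", sum(p.data.size for p in model.aux_head.parameters()))
    if cfg.lstm_layers:
        row(
            f"Bi-LSTM x{cfg.lstm_layers} (hidden {cfg.lstm_hidden}/dir)",
            sum(p.data.size for p in model.lstm.parameters()),
        )
    row("main head: dense softmax", sum(p.data.size for p in model.main_head.parameters()))
    lines.append("-" * 49)
    lines.append(f"{'total trainable parameters':<38s} {total:>10,d}")
    lines.append(f"{'':<38s} {total / 1e6:>9.1f}M")
    return "\n".join(lines)
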