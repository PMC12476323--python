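"""CNN classifiers, training protocol and metric aggregation.

Two architectures classify spectrogram images into the five tissue classes:

* **NeedleNet** — four convolutional blocks (64, 128, 256, 512 filters;
  kernel 3, stride 2, padding 1), each block being conv → ReLU → dropout(0.2)
  → batch-norm, followed by adaptive average pooling to 1×1 and one fully
  connected layer. The adaptive pooling makes the network input-size
  agnostic, so differently shaped spectrogram representations are comparable
  without resizing.
* **ResNet-34** — the standard 34-layer residual network with its final
  fully connected layer replaced (1000 → 5) and single-channel spectrograms
  replicated to 3 channels at input.

Training follows one protocol for every model–dataset pair: 150 epochs, SGD
with learning rate 0.01 and momentum 0.9, batch size 32, cross-entropy loss,
5-fold cross-validation on the recording-grouped split. Metrics (accuracy,
macro precision, macro F1) are logged after every epoch on both splits;
results are summarized as the best value observed over all folds/epochs and
the average of the final-epoch values across folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, precision_score

from . import nn
from .features import FeatureArchive
from .split import FoldAssignment
from .synthetic import CorpusManifest

MIN_INPUT_SIDE = 16  # four stride-2 convolutions need >= 16 pixels per side


@dataclass
class NeedleNetConfig:
    block_filters: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 3
    stride: int = 2
    padding: int = 1
    dropout_p: float = 0.2
    n_classes: int = 5
    in_channels: int = 1
    # conv -> ReLU -> dropout -> batch-norm, as specified; the conventional
    # conv -> BN -> ReLU -> dropout order is available as "conv_bn_relu_dropout"
    block_order: str = "conv_relu_dropout_bn"

    def validate(self) -> None:
        if len(self.block_filters) != 4:
            raise ValueError("NeedleNet has exactly 4 convolutional blocks")
        if any(b >= a for a, b in zip(self.block_filters[1:], self.block_filters)):
            raise ValueError("block filters must be strictly increasing")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.block_order not in ("conv_relu_dropout_bn", "conv_bn_relu_dropout"):
            raise ValueError(f"unknown block_order {self.block_order!r}")


@dataclass
class TrainConfig:
    epochs: int = 150
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    n_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class NeedleNet(nn.Module):
    """Four stride-2 conv blocks + adaptive average pooling + linear head."""

    def __init__(self, config: NeedleNetConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        config = config or NeedleNetConfig()
        config.validate()
        rng = rng or np.random.default_rng()
        self.config = config
        layers: list[nn.Module] = []
        in_ch = config.in_channels
        for out_ch in config.block_filters:
            conv = nn.Conv2d(in_ch, out_ch, config.kernel, config.stride, config.padding, rng=rng)
            if config.block_order == "conv_relu_dropout_bn":
                block = [conv, nn.ReLU(), nn.Dropout(config.dropout_p, rng=rng), nn.BatchNorm2d(out_ch)]
            else:
                block = [conv, nn.BatchNorm2d(out_ch), nn.ReLU(), nn.Dropout(config.dropout_p, rng=rng)]
            layers.extend(block)
            in_ch = out_ch
        self.body = nn.Sequential(*layers)
        self.pool = nn.AdaptiveAvgPool()
        self.head = nn.Linear(config.block_filters[-1], config.n_classes, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError(f"expected (batch, channels, H, W) input, got shape {x.shape}")
        if x.shape[2] < MIN_INPUT_SIDE or x.shape[3] < MIN_INPUT_SIDE:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} too small: four stride-2 convolutions "
                f"require at least {MIN_INPUT_SIDE} pixels per side"
            )
        return self.head(self.pool(self.body(x.astype(np.float32))))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(self.pool.backward(self.head.backward(grad)))


def build_needlenet(config: NeedleNetConfig | None = None, seed: int = 0) -> NeedleNet:
    """Seeded NeedleNet construction (weights and dropout streams)."""
    return NeedleNet(config, rng=np.random.default_rng(seed))


def needlenet_parameter_count(config: NeedleNetConfig | None = None) -> int:
    """Closed-form trainable parameter tally (conv + batch-norm + linear)."""
    config = config or NeedleNetConfig()
    total = 0
    in_ch = config.in_channels
    for out_ch in config.block_filters:
        total += config.kernel * config.kernel * in_ch * out_ch + out_ch  # conv W + b
        total += 2 * out_ch  # batch-norm gamma + beta
        in_ch = out_ch
    total += config.block_filters[-1] * config.n_classes + config.n_classes
    return total


# ---------------------------------------------------------------------------
# ResNet-34


class _BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator) -> None:
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride, 1, rng=rng, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, 1, 1, rng=rng, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.relu2 = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng, bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return self.relu2(out + identity)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(grad)
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad)))))
        if self.down_conv is None:
            d_skip = grad
        else:
            d_skip = self.down_conv.backward(self.down_bn.backward(grad))
        return d_main + d_skip


class _ChannelReplicate(nn.Module):
    """Replicate a single input channel to ``n`` channels (grayscale → RGB)."""

    def __init__(self, n: int = 3) -> None:
        self.n = n

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == self.n:
            self._replicated = False
            return x
        if x.shape[1] != 1:
            raise ValueError(f"expected 1 or {self.n} channels, got {x.shape[1]}")
        self._replicated = True
        return np.repeat(x, self.n, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if not self._replicated:
            return grad
        return grad.sum(axis=1, keepdims=True)


class ResNet34(nn.Module):
    """Standard ResNet-34 with an ``n_classes``-way head and 1→3 channel adapter."""

    LAYER_BLOCKS = (3, 4, 6, 3)
    LAYER_CHANNELS = (64, 128, 256, 512)

    def __init__(self, n_classes: int = 5, rng: np.random.Generator | None = None) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = rng or np.random.default_rng()
        self.adapter = _ChannelReplicate(3)
        self.stem = nn.Sequential(
            nn.Conv2d(3, 64, 7, 2, 3, rng=rng, bias=False),
            nn.BatchNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        )
        blocks: list[nn.Module] = []
        in_ch = 64
        for ch, n_blocks in zip(self.LAYER_CHANNELS, self.LAYER_BLOCKS):
            for b in range(n_blocks):
                stride = 2 if (b == 0 and ch != 64) else 1
                blocks.append(_BasicBlock(in_ch, ch, stride, rng))
                in_ch = ch
        self.blocks = nn.Sequential(*blocks)
        self.pool = nn.AdaptiveAvgPool()
        self.fc = nn.Linear(512, n_classes, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.adapter(x.astype(np.float32))
        return self.fc(self.pool(self.blocks(self.stem(x))))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.stem.backward(self.blocks.backward(self.pool.backward(self.fc.backward(grad))))
        return self.adapter.backward(grad)


def build_resnet34_adapter(n_classes: int = 5, pretrained: bool = False, seed: int = 0) -> ResNet34:
    """ResNet-34 with the final layer sized for ``n_classes``.

    ``pretrained`` requires an ImageNet weight cache, which this fully
    offline implementation does not ship; requesting it raises with advice
    to use ``pretrained=False`` (random initialization, fully reproducible).
    """
    if pretrained:
        raise RuntimeError(
            "pretrained ResNet-34 weights are not available offline; "
            "pass pretrained=False (CLI: --no-pretrained) for random initialization"
        )
    return ResNet34(n_classes=n_classes, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(
    predicted: np.ndarray, actual: np.ndarray, n_classes: int = 5, average: str = "macro"
) -> tuple[float, float, float]:
    """(accuracy, precision, F1) for a multiclass prediction.

    Precision and F1 are macro-averaged over all ``n_classes`` classes by
    default: classes absent from both prediction and truth contribute 0 and
    are counted in the unweighted mean. ``average="weighted"`` is available.
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must be equal-length non-empty sequences")
    labels = list(range(n_classes))
    acc = float(np.mean(predicted == actual))
    prec = float(precision_score(actual, predicted, labels=labels, average=average, zero_division=0))
    f1 = float(f1_score(actual, predicted, labels=labels, average=average, zero_division=0))
    return acc, prec, f1


@dataclass
class MetricsReport:
    """Per-epoch cross-validation metrics with the study's two aggregates.

    ``best`` is the maximum of each test metric over all folds and epochs;
    ``average_final`` is the mean over folds of the final-epoch test metrics.
    """

    per_fold_per_epoch: pd.DataFrame  # fold, epoch, split, loss, accuracy, precision, f1
    label: str = ""

    def _test_rows(self) -> pd.DataFrame:
        return self.per_fold_per_epoch[self.per_fold_per_epoch["split"] == "test"]

    @property
    def best(self) -> dict[str, float]:
        t = self._test_rows()
        return {m: float(t[m].max()) for m in ("accuracy", "precision", "f1")}

    @property
    def average_final(self) -> dict[str, float]:
        t = self._test_rows()
        final = t[t["epoch"] == t["epoch"].max()]
        return {m: float(final[m].mean()) for m in ("accuracy", "precision", "f1")}

    def summary(self) -> str:
        best, avg = self.best, self.average_final
        lines = [
            f"Cross-validation results{': ' + self.label if self.label else ''}",
            f"  folds: {self.per_fold_per_epoch['fold'].nunique()}, "
            f"epochs: {self.per_fold_per_epoch['epoch'].max()}",
            "  metric      best      average final",
        ]
        for m in ("accuracy", "precision", "f1"):
            lines.append(f"  {m:<10}  {best[m]:>7.2%}  {avg[m]:>10.2%}")
        return "\n".join(lines)


def summarize_runs(reports: list[MetricsReport], labels: list[str] | None = None) -> pd.DataFrame:
    """Results table: one row per configuration, ``best% (average%)`` cells."""
    if not reports:
        raise ValueError("no reports to summarize")
    if labels is None:
        labels = [r.label or f"run {i}" for i, r in enumerate(reports)]
    if len(labels) != len(reports):
        raise ValueError("labels and reports must have equal length")
    rows = []
    for label, rep in zip(labels, reports):
        best, avg = rep.best, rep.average_final
        rows.append({
            "Configuration": label,
            "Accuracy": f"{best['accuracy']:.2%} ({avg['accuracy']:.2%})",
            "Precision": f"{best['precision']:.2%} ({avg['precision']:.2%})",
            "F1 Score": f"{best['f1']:.2%} ({avg['f1']:.2%})",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validated training


def standardize_segments(features: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization per segment (per 2-D image)."""
    x = features.astype(np.float32)
    mean = x.mean(axis=(1, 2), keepdims=True)
    std = x.std(axis=(1, 2), keepdims=True)
    return (x - mean) / np.maximum(std, 1e-8)


def _build_model(model_spec: str, n_classes: int, seed: int) -> nn.Module:
    if model_spec == "needlenet":
        return build_needlenet(NeedleNetConfig(n_classes=n_classes), seed=seed)
    if model_spec == "resnet34":
        return build_resnet34_adapter(n_classes=n_classes, pretrained=False, seed=seed)
    raise ValueError(f"unknown model_spec {model_spec!r} (expected 'needlenet' or 'resnet34')")


def _eval_pass(model: nn.Module, x: np.ndarray, y: np.ndarray, batch_size: int,
               n_classes: int) -> tuple[float, float, float, float]:
    model.eval()
    losses, preds = [], []
    for i in range(0, len(x), batch_size):
        logits = model(x[i : i + batch_size])
        loss, _ = nn.softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * logits.shape[0])
        preds.append(logits.argmax(axis=1))
    pred = np.concatenate(preds)
    acc, prec, f1 = compute_metrics(pred, y, n_classes=n_classes)
    return float(np.sum(losses) / len(x)), acc, prec, f1


def train_crossval(
    features: FeatureArchive | str | Path,
    folds: FoldAssignment,
    manifest: CorpusManifest | None = None,
    model_spec: str = "needlenet",
    config: TrainConfig | None = None,
    n_classes: int = 5,
    label: str = "",
) -> MetricsReport:
    """Train and evaluate a model under recording-grouped K-fold cross-validation.

    For each fold ``k`` the model is trained from scratch on all other folds
    and tested on fold ``k``; per-segment-standardized spectrograms are the
    inputs. Train-split metrics are accumulated from the training batches;
    test metrics come from an evaluation pass after each epoch. One master
    seed fans out to per-fold seeds for initialization, shuffling and dropout,
    so runs are bit-reproducible.
    """
    if isinstance(features, (str, Path)):
        features = FeatureArchive.load(features)
    config = config or TrainConfig()
    config.validate()

    x = standardize_segments(features.features)[:, None, :, :]  # (n, 1, H, W)
    y = features.labels.astype(np.int64)
    seg_folds = np.asarray([folds.fold_of_recording[r] for r in features.recording_ids])

    ss = np.random.SeedSequence(config.seed)
    fold_seeds = ss.spawn(folds.n_folds)
    records = []
    for k in range(folds.n_folds):
        train_idx = np.nonzero(seg_folds != k)[0]
        test_idx = np.nonzero(seg_folds == k)[0]
        if train_idx.size == 0 or test_idx.size == 0:
            raise ValueError(f"fold {k} leaves an empty train or test split")
        model_seed, shuffle_seed = fold_seeds[k].spawn(2)
        model = _build_model(model_spec, n_classes, seed=model_seed)
        optimizer = nn.SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
        shuffle_rng = np.random.default_rng(shuffle_seed)

        for epoch in range(1, config.epochs + 1):
            model.train()
            order = shuffle_rng.permutation(train_idx)
            batch_losses, batch_preds, batch_truth = [], [], []
            for i in range(0, order.size, config.batch_size):
                idx = order[i : i + config.batch_size]
                logits = model(x[idx])
                loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
                model.zero_grad()
                model.backward(dlogits)
                optimizer.step()
                batch_losses.append(loss * idx.size)
                batch_preds.append(logits.argmax(axis=1))
                batch_truth.append(y[idx])
            train_pred = np.concatenate(batch_preds)
            train_truth = np.concatenate(batch_truth)
            tr_acc, tr_prec, tr_f1 = compute_metrics(train_pred, train_truth, n_classes=n_classes)
            records.append({
                "fold": k, "epoch": epoch, "split": "train",
                "loss": float(np.sum(batch_losses) / order.size),
                "accuracy": tr_acc, "precision": tr_prec, "f1": tr_f1,
            })
            te_loss, te_acc, te_prec, te_f1 = _eval_pass(
                model, x[test_idx], y[test_idx], config.batch_size, n_classes
            )
            records.append({
                "fold": k, "epoch": epoch, "split": "test", "loss": te_loss,
                "accuracy": te_acc, "precision": te_prec, "f1": te_f1,
            })
    return MetricsReport(per_fold_per_epoch=pd.DataFrame(records), label=label)
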