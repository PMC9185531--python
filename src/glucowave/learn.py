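"""Training and evaluation of the five-class concentration classifier.

The measurement campaign yields on the order of a thousand labelled
records, split 85/10/5 into training, validation and test sets.  The
training set is optionally expanded with white-noise-perturbed copies to
compensate for the small sample, and a residual CNN + bi-LSTM network is
trained with momentum SGD on the CWT scalogram tensors.  Because the
tensors retain echo phase, the classifier stays accurate across power
cycles where the per-session energy calibration line fails.

The module is organised around a model object:
:class:`ConcentrationClassifier` holds the data and hyperparameters,
``fit()`` runs the optimisation and returns a :class:`ClassifierResults`
carrying the trained network, the per-epoch training curve and accuracy
helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from glucowave.config import DEFAULT_CONCENTRATIONS
from glucowave.nn.network import CRNN
from glucowave.nn.optim import SGD

DEFAULT_RATIOS = (0.85, 0.10, 0.05)


class TrainingError(RuntimeError):
    """Raised when optimisation diverges (non-finite loss)."""


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test index lists covering a dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float] = DEFAULT_RATIOS
    seed: int = 0

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index lists overlap")


def split_dataset(
    n: int, ratios: Sequence[float] = DEFAULT_RATIOS, seed: int = 0
) -> DatasetSplit:
    """Random 85/10/5 split (by default) of ``n`` records.

    Validation and test sizes are ``round(n * ratio)``; the remainder goes
    to the training set, so 1000 records split exactly 850/100/50.  The
    permutation is a deterministic function of the seed.
    """
    if n < 20:
        raise ValueError("need at least 20 records to split")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n_val = round(n * ratios[1])
    n_test = round(n * ratios[2])
    n_train = n - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
        ratios=ratios,
        seed=seed,
    )


def augment_white_noise(
    tensors: np.ndarray,
    labels: np.ndarray,
    copies: int = 3,
    sigma: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a training set with white-noise-perturbed copies.

    Parameters
    ----------
    tensors, labels
        Originals; returned unmodified at the head of the output.
    copies
        Number of noisy copies per original; output size is
        ``(copies + 1) * len(tensors)``.
    sigma
        Noise standard deviation.  ``None`` uses 5% of the originals'
        global standard deviation.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    tensors = np.asarray(tensors)
    labels = np.asarray(labels)
    if sigma is None:
        sigma = 0.05 * float(tensors.std())
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if copies == 0:
        return tensors, labels
    rng = np.random.default_rng(seed)
    out = [tensors]
    out_labels = [labels]
    for _ in range(copies):
        out.append(tensors + sigma * rng.standard_normal(tensors.shape))
        out_labels.append(labels)
    return np.concatenate(out), np.concatenate(out_labels)


# ---------------------------------------------------------------------------
# hyperparameters


@dataclass(frozen=True)
class HyperparameterBounds:
    """Searchable box for the three tunable network hyperparameters."""

    conv_kernel_size: tuple[int, int] = (3, 7)
    conv_stride: tuple[int, int] = (1, 2)
    lstm_hidden_size: tuple[int, int] = (8, 64)

    def as_list(self) -> list[tuple[float, float]]:
        return [
            tuple(map(float, self.conv_kernel_size)),
            tuple(map(float, self.conv_stride)),
            tuple(map(float, self.lstm_hidden_size)),
        ]


@dataclass(frozen=True)
class HyperparameterVector:
    """Concrete network hyperparameters: stem kernel/stride, LSTM width."""

    conv_kernel_size: int = 3
    conv_stride: int = 2
    lstm_hidden_size: int = 16

    def validate(self, bounds: HyperparameterBounds) -> None:
        if self.conv_kernel_size % 2 != 1:
            raise ValueError("conv kernel size must be odd")
        for name in ("conv_kernel_size", "conv_stride", "lstm_hidden_size"):
            lo, hi = getattr(bounds, name)
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside bounds [{lo}, {hi}]")


#: fixed default configuration, the baseline the optimiser must beat
DEFAULT_HYPERPARAMETERS = HyperparameterVector(
    conv_kernel_size=3, conv_stride=2, lstm_hidden_size=16
)


def build_network(
    h: HyperparameterVector,
    scale: str = "reduced",
    seed: int = 0,
    bounds: HyperparameterBounds | None = None,
    n_classes: int = 5,
    dtype: type = np.float64,
) -> CRNN:
    """Instantiate an (untrained) classifier for a hyperparameter vector."""
    h.validate(bounds or HyperparameterBounds())
    return CRNN(
        conv_kernel_size=h.conv_kernel_size,
        conv_stride=h.conv_stride,
        lstm_hidden_size=h.lstm_hidden_size,
        scale=scale,
        seed=seed,
        n_classes=n_classes,
        dtype=dtype,
    )


def evaluate(model: CRNN, tensors: np.ndarray, labels: np.ndarray, batch: int = 64) -> float:
    """Classification accuracy of ``model`` on a labelled set."""
    tensors = np.asarray(tensors)
    labels = np.asarray(labels)
    if len(tensors) == 0:
        raise ValueError("cannot evaluate on an empty set")
    correct = 0
    for start in range(0, len(tensors), batch):
        pred = model.predict(tensors[start : start + batch])
        correct += int(np.sum(pred == labels[start : start + batch]))
    return correct / len(tensors)


# ---------------------------------------------------------------------------
# the model object


def labels_from_concentrations(
    concentrations: Sequence[float],
    classes: Sequence[float] = DEFAULT_CONCENTRATIONS,
) -> np.ndarray:
    """Map concentration values to class indices; unknown values raise.

    The classifier is only valid for the concentrations it was trained on,
    so an unseen concentration is an error, not a nearest-match.
    """
    classes = np.asarray(classes, dtype=float)
    out = np.empty(len(concentrations), dtype=int)
    for i, c in enumerate(concentrations):
        match = np.nonzero(np.isclose(classes, c, rtol=0, atol=1e-9))[0]
        if match.size == 0:
            raise ValueError(f"concentration {c} is not one of the known classes")
        out[i] = match[0]
    return out


@dataclass
class TrainingCurve:
    epoch_losses: list[float] = field(default_factory=list)
    epoch_val_accuracy: list[float] = field(default_factory=list)


class ConcentrationClassifier:
    """Model object: scalogram tensors + labels + training configuration.

    Parameters
    ----------
    tensors
        (n, n_scales, N, 4) array of zero-mean scalogram tensors.
    labels
        Integer class indices (use :func:`labels_from_concentrations` to
        map concentration values).
    hyperparameters, scale
        Network configuration; ``reduced`` is the 4-block desk-scale
        backbone, ``full`` the 18-layer one.
    lr, momentum, batch_size, epochs
        Momentum-SGD settings (defaults 0.01 / 0.9 / 32 / 30).
    augment_copies, augment_sigma
        White-noise augmentation of the training set; ``sigma=None`` uses
        5% of the training tensors' standard deviation.
    """

    def __init__(
        self,
        tensors: np.ndarray,
        labels: np.ndarray,
        split: DatasetSplit | None = None,
        hyperparameters: HyperparameterVector = DEFAULT_HYPERPARAMETERS,
        scale: str = "reduced",
        lr: float = 0.01,
        momentum: float = 0.9,
        batch_size: int = 32,
        epochs: int = 30,
        lr_decay_at: tuple[float, ...] = (0.6, 0.85),
        lr_decay_factor: float = 0.2,
        augment_copies: int = 0,
        augment_sigma: float | None = None,
        n_classes: int = 5,
        dtype: type = np.float64,
        eval_curve: bool = True,
    ) -> None:
        self.dtype = np.dtype(dtype)
        self.eval_curve = eval_curve
        self.tensors = np.asarray(tensors, dtype=self.dtype)
        self.labels = np.asarray(labels, dtype=int)
        if len(self.tensors) != len(self.labels):
            raise ValueError("tensors and labels differ in length")
        self.split = split or split_dataset(len(self.labels))
        if len(self.split.train) == 0 or len(self.split.validation) == 0:
            raise ValueError("train and validation sets must be nonempty")
        self.hyperparameters = hyperparameters
        self.scale = scale
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_decay_at = tuple(lr_decay_at)
        self.lr_decay_factor = lr_decay_factor
        self.augment_copies = augment_copies
        self.augment_sigma = augment_sigma
        self.n_classes = n_classes

    def fit(self, seed: int = 0, verbose: bool = False) -> "ClassifierResults":
        """Train with momentum SGD; reproducible for a fixed seed."""
        net = build_network(
            self.hyperparameters,
            scale=self.scale,
            seed=seed,
            n_classes=self.n_classes,
            dtype=self.dtype,
        )
        x_train = self.tensors[self.split.train]
        y_train = self.labels[self.split.train]
        if self.augment_copies > 0:
            x_train, y_train = augment_white_noise(
                x_train,
                y_train,
                copies=self.augment_copies,
                sigma=self.augment_sigma,
                seed=seed + 1,
            )
        x_val = self.tensors[self.split.validation]
        y_val = self.labels[self.split.validation]
        opt = SGD(net.parameters(), lr=self.lr, momentum=self.momentum)
        rng = np.random.default_rng(seed + 2)
        curve = TrainingCurve()
        n = len(x_train)
        decay_epochs = {int(frac * self.epochs) for frac in self.lr_decay_at}
        for epoch in range(self.epochs):
            if epoch in decay_epochs:
                opt.lr *= self.lr_decay_factor
            net.set_training(True)
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                opt.zero_grad()
                loss = net.loss_and_grad(x_train[idx], y_train[idx])
                if not math.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss {loss} at epoch {epoch}, "
                        f"batch starting {start} (lr={self.lr})"
                    )
                opt.step()
                losses.append(loss)
            curve.epoch_losses.append(float(np.mean(losses)))
            if self.eval_curve or epoch == self.epochs - 1:
                self._refresh_batchnorm(net, x_train, rng)
                net.set_training(False)
                curve.epoch_val_accuracy.append(evaluate(net, x_val, y_val))
            else:
                net.set_training(False)
            if verbose:
                print(
                    f"epoch {epoch + 1:3d}  loss {curve.epoch_losses[-1]:.4f}  "
                    f"val acc {curve.epoch_val_accuracy[-1]:.3f}"
                )
        return ClassifierResults(model=self, network=net, curve=curve, seed=seed)

    @staticmethod
    def _refresh_batchnorm(
        net: CRNN, x_train: np.ndarray, rng: np.random.Generator, n_batches: int = 2
    ) -> None:
        """Re-estimate batch-norm running statistics at the current weights.

        The exponential running averages collected during an epoch lag the
        moving weights; a few large forward passes in training mode (no
        gradient step) settle them before the held-out evaluation
        ("precise BN").
        """
        from glucowave.nn.layers import BatchNorm2d, _walk

        bns = [m for m in _walk(net) if isinstance(m, BatchNorm2d)]
        saved = [bn.momentum for bn in bns]
        net.set_training(True)
        n = len(x_train)
        batch = min(192, n)
        for i in range(n_batches):
            for bn in bns:  # incremental exact average of batch statistics
                bn.momentum = 1.0 / (i + 1)
            idx = rng.integers(0, n, size=batch)
            net.forward(x_train[idx])
        for bn, m in zip(bns, saved):
            bn.momentum = m
        net.set_training(False)


@dataclass
class ClassifierResults:
    """Trained classifier with its training curve and evaluation helpers."""

    model: ConcentrationClassifier
    network: CRNN
    curve: TrainingCurve
    seed: int

    @property
    def validation_accuracy(self) -> float:
        return self.curve.epoch_val_accuracy[-1]

    def accuracy(self, which: str = "validation") -> float:
        idx = getattr(self.model.split, which)
        return evaluate(self.network, self.model.tensors[idx], self.model.labels[idx])

    def predict_proba(self, tensors: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(tensors)

    def summary(self) -> str:
        h = self.model.hyperparameters
        lines = [
            "Concentration classifier (residual CNN + 2 bi-LSTM layers)",
            "-" * 60,
            f"  backbone scale        {self.model.scale}",
            f"  conv kernel / stride  {h.conv_kernel_size} / {h.conv_stride}",
            f"  LSTM hidden width     {h.lstm_hidden_size}",
            f"  optimizer             SGD(momentum={self.model.momentum}, "
            f"lr={self.model.lr})",
            f"  epochs / batch        {self.model.epochs} / {self.model.batch_size}",
            f"  final train loss      {self.curve.epoch_losses[-1]:.4f}",
            f"  validation accuracy   {self.validation_accuracy:.3f}",
        ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.curve.epoch_losses) + 1)
        ax.plot(epochs, self.curve.epoch_losses, label="train loss")
        ax.plot(epochs, self.curve.epoch_val_accuracy, label="validation accuracy")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax
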