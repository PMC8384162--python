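"""Training, prediction, genome scanning and evaluation of the G4 network.

The full model scores a 201-bp window from its one-hot sequence plus the
mean chromatin accessibility over the window; the sequence-only ablation
(``use_accessibility=False``) is the same network without the scalar
input, used to quantify what accessibility contributes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .datasets import LabeledDataset
from .io import GenomicRegion, SignalTrack, encode_batch
from .nn import ConvNet

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture constants.

    Defaults are the published hyperparameters: 900 kernels of width 20 bp
    with ReLU activation, average pooling over 12-bp windows, no dropout,
    a 100-unit dense layer, 20 training epochs and the RMSprop optimizer,
    on 201-bp inputs.
    """

    n_kernels: int = 900
    kernel_size: int = 20
    pool_size: int = 12
    dropout_rate: float = 0.0
    dense_units: int = 100
    epochs: int = 20
    input_length: int = 201
    use_accessibility: bool = True
    batch_size: int = 128
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.kernel_size > self.input_length:
            raise ValueError("kernel_size exceeds input_length")
        if self.pool_size > self.input_length - self.kernel_size + 1:
            raise ValueError("pool_size exceeds the convolution output length")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def conv_output_length(self) -> int:
        return self.input_length - self.kernel_size + 1

    @property
    def pooled_length(self) -> int:
        return self.conv_output_length // self.pool_size

    @property
    def fused_length(self) -> int:
        """Length of the feature vector entering the dense layer."""
        return self.n_kernels + (1 if self.use_accessibility else 0)


def build_model(spec: ModelSpec, seed: int = 0) -> ConvNet:
    """Instantiate the untrained network for a spec (weights seeded)."""
    return ConvNet(
        n_kernels=spec.n_kernels,
        kernel_size=spec.kernel_size,
        pool_size=spec.pool_size,
        dropout_rate=spec.dropout_rate,
        dense_units=spec.dense_units,
        input_length=spec.input_length,
        use_accessibility=spec.use_accessibility,
        seed=seed,
    )


@dataclass
class TrainedModel:
    """A fitted network plus the accessibility rescaling it was trained with.

    Accessibility is normalised by the 99th percentile of the positive
    training examples' mean signal and clipped to [0, 1]; the divisor is
    stored so predictions on new data reuse the training-time scale.
    """

    spec: ModelSpec
    net: ConvNet
    accessibility_scale: float = 1.0
    training_history: list[dict] = field(default_factory=list)
    seed: int = 0

    def _normalise_acc(self, accessibility) -> np.ndarray:
        acc = np.asarray(accessibility, dtype=np.float32)
        return np.clip(acc / self.accessibility_scale, 0.0, 1.0)

    def predict(
        self,
        sequences: Sequence[str],
        accessibility: Sequence[float] | None = None,
    ) -> np.ndarray:
        """Score sequences; probabilities in [0, 1], order preserved."""
        sequences = list(sequences)
        for i, s in enumerate(sequences):
            if len(s) != self.spec.input_length:
                raise ValueError(
                    f"sequence {i} has length {len(s)}, "
                    f"expected {self.spec.input_length}"
                )
        if not self.spec.use_accessibility:
            if accessibility is not None:
                warnings.warn(
                    "model was trained without accessibility; input ignored",
                    stacklevel=2,
                )
            acc = np.zeros(len(sequences), dtype=np.float32)
        else:
            if accessibility is None:
                raise ValueError("this model requires accessibility values")
            if len(accessibility) != len(sequences):
                raise ValueError("sequence/accessibility length mismatch")
            acc = self._normalise_acc(accessibility)
        X = encode_batch(sequences)
        return self.net.predict_proba(X, acc)

    def predict_encoded(self, X: np.ndarray, accessibility=None) -> np.ndarray:
        """Score pre-encoded (n, L, 4) inputs (raw accessibility units)."""
        if accessibility is None or not self.spec.use_accessibility:
            acc = np.zeros(X.shape[0], dtype=np.float32)
        else:
            acc = self._normalise_acc(accessibility)
        return self.net.predict_proba(X, acc)

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": _FORMAT_VERSION,
            "spec": asdict(self.spec),
            "accessibility_scale": self.accessibility_scale,
            "training_history": self.training_history,
            "seed": self.seed,
        }
        with open(path, "wb") as fh:  # keep the exact path (np.savez appends .npz)
            np.savez(
                fh,
                __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                **self.net.params,
            )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        try:
            archive = np.load(path)
            meta = json.loads(bytes(archive["__meta__"]).decode())
        except Exception as exc:
            raise ValueError(f"not a readable model bundle: {path} ({exc})") from exc
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"model bundle {path} has format version "
                f"{meta.get('format_version')}, expected {_FORMAT_VERSION}"
            )
        spec = ModelSpec(**meta["spec"])
        net = build_model(spec, seed=meta["seed"])
        for key in net.params:
            net.params[key] = archive[key].copy()
        return cls(
            spec=spec,
            net=net,
            accessibility_scale=meta["accessibility_scale"],
            training_history=meta["training_history"],
            seed=meta["seed"],
        )


def train(
    spec: ModelSpec,
    dataset: LabeledDataset,
    seed: int = 0,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the network on the dataset's training split.

    Binary cross-entropy is minimised with RMSprop for ``spec.epochs``
    epochs; validation loss/accuracy are recorded per epoch when the
    dataset has a validation split. All randomness derives from ``seed``.
    """
    X, acc, y = dataset.arrays("train")
    if np.unique(y).size < 2:
        raise ValueError("training split must contain both classes")
    pos_acc = acc[y == 1]
    scale = float(np.percentile(pos_acc, 99)) if pos_acc.size else 1.0
    if scale <= 0:
        scale = 1.0
    net = build_model(spec, seed=seed)
    model = TrainedModel(spec=spec, net=net, accessibility_scale=scale, seed=seed)
    acc_n = model._normalise_acc(acc) if spec.use_accessibility else np.zeros_like(acc)
    validation = None
    if any(s == "validation" for s in dataset.split):
        Xv, accv, yv = dataset.arrays("validation")
        accv_n = model._normalise_acc(accv) if spec.use_accessibility else np.zeros_like(accv)
        validation = (Xv, accv_n, yv)
    model.training_history = net.fit(
        X, acc_n, y,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        seed=seed,
        validation=validation,
        learning_rate=spec.learning_rate,
        verbose=verbose,
    )
    return model


# ---------------------------------------------------------------------------
# genome scanning


@dataclass(frozen=True)
class BinPrediction:
    region: GenomicRegion
    score: float
    flagged: bool = False  # >= 90% ambiguous bases; score forced to 0


def scan_genome(
    model: TrainedModel,
    genome,
    track: SignalTrack | None = None,
    bin_size: int = 200,
    batch_size: int = 512,
) -> list[BinPrediction]:
    """Tile every chromosome into fixed bins and score each.

    The model window shares the bin's start and extends
    ``input_length - bin_size`` bases rightward; windows running past the
    chromosome end are padded with N (all-zero rows). Bins whose window is
    >= 90% non-ACGT are emitted flagged with score 0.
    """
    L = model.spec.input_length
    if bin_size > L:
        raise ValueError("bin_size must not exceed the model input length")
    out: list[BinPrediction] = []
    chroms = list(genome.keys()) if hasattr(genome, "keys") else list(genome)
    for chrom in chroms:
        record = genome[chrom]
        clen = len(record)
        chrom_seq = record if isinstance(record, str) else str(record[:])
        chrom_seq = chrom_seq.upper()
        starts = list(range(0, clen, bin_size))
        windows, regions, flags = [], [], []
        for s in starts:
            end = min(s + bin_size, clen)
            regions.append(GenomicRegion(chrom, s, end))
            win = chrom_seq[s : s + L]
            win = win + "N" * (L - len(win))
            nfrac = sum(1 for b in win if b not in "ACGT") / L
            flags.append(nfrac >= 0.9)
            windows.append(win)
        if track is not None and model.spec.use_accessibility:
            acc = np.array([track.mean_signal(r) for r in regions], dtype=np.float32)
        else:
            acc = np.zeros(len(regions), dtype=np.float32)
        for i in range(0, len(windows), batch_size):
            X = encode_batch(windows[i : i + batch_size])
            scores = model.predict_encoded(X, acc[i : i + batch_size])
            for region, flag, score in zip(
                regions[i : i + batch_size], flags[i : i + batch_size], scores
            ):
                out.append(
                    BinPrediction(region, 0.0 if flag else float(score), flag)
                )
    return out


def write_bin_predictions(bins: Sequence[BinPrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.region.chrom}\t{b.region.start}\t{b.region.end}\t{b.score:.6g}\n")


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> dict:
    """Threshold-free and thresholded classification metrics.

    Returns AUROC (trapezoidal over all thresholds), AUPR (step
    interpolation of the precision-recall curve), plus accuracy and
    FDR = FP / (FP + TP) at ``threshold``, together with the full curves.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("both classes are required for AUROC/AUPR")
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    fpr, tpr, roc_thresholds = roc_curve(labels, scores)
    precision, recall, pr_thresholds = precision_recall_curve(labels, scores)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "accuracy": float(np.mean(calls == (labels == 1))),
        "fdr": float(fdr),
        "threshold": threshold,
        "roc_curve": (fpr, tpr, roc_thresholds),
        "pr_curve": (precision, recall, pr_thresholds),
    }
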