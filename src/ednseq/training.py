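"""Training and evaluation protocol.

Models are fit with binary cross-entropy and Adam; after every epoch the
Matthews correlation coefficient (MCC) on the validation split is
computed and training stops once it has not strictly improved for
``patience`` consecutive epochs, restoring the best-epoch weights.
Evaluation aggregates test MCC over several independently seeded runs
(mean +/- sample standard deviation, five runs by convention) and
methods are compared with a classical paired t-test over matched
(dataset x run) MCC values.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import (
    DEFAULT_KERNEL,
    DEFAULT_SCALES,
    EdnValidationError,
    edn_multiscale,
)
from .data import LabeledDataset
from .model import BranchSelection, HybridClassifier, ModelConfig, build_model
from . import nn

__all__ = [
    "TrainConfig",
    "EvalReport",
    "PairedTestResult",
    "mcc",
    "mcc_from_predictions",
    "train_with_early_stopping",
    "EpochRecord",
    "PipelineSpec",
    "encode_dataset",
    "run_pipeline_once",
    "evaluate_runs",
    "paired_ttest",
]


# --------------------------------------------------------------------------
# Matthews correlation coefficient
# --------------------------------------------------------------------------


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC from confusion counts; 0 when any denominator factor is 0."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise EdnValidationError(f"confusion counts must be non-negative, got {counts}")
    if all(c == 0 for c in counts):
        raise EdnValidationError("all confusion counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return mcc(tp, fp, tn, fn)


# --------------------------------------------------------------------------
# Training with MCC early stopping
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization settings; defaults favor the short benchmark-style
    sequences this package targets (Adam 1e-3, batch 32)."""

    patience: int = 4
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    threshold: float = 0.5  # decision threshold for validation/test MCC

    def __post_init__(self) -> None:
        if self.patience < 1 or self.max_epochs < 1:
            raise EdnValidationError("patience and max_epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    valid_mcc: float


def train_with_early_stopping(
    model: HybridClassifier,
    train: tuple[dict, np.ndarray],
    valid: tuple[dict, np.ndarray],
    config: TrainConfig,
    verbose: bool = False,
) -> list[EpochRecord]:
    """Fit ``model`` in place; returns the per-epoch history.

    ``train``/``valid`` are ``({"hf": ..., "ms": ...}, labels)`` pairs.
    "Improvement" means strictly greater validation MCC; after
    ``patience`` epochs without one (or at ``max_epochs``) the weights
    of the best epoch are restored.
    """
    x_train, y_train = train
    x_valid, y_valid = valid
    y_train = np.asarray(y_train, dtype=float)
    if y_valid.size == 0:
        raise EdnValidationError("validation split is empty")
    if not set(np.unique(y_train)) <= {0.0, 1.0}:
        raise EdnValidationError("labels must be binary 0/1")

    rng = np.random.default_rng(config.seed)
    model._rng = np.random.default_rng(config.seed + 1)  # dropout masks
    optimizer = nn.Adam(model.modules(), lr=config.learning_rate)
    n = y_train.size

    history: list[EpochRecord] = []
    best_mcc = -np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            hf = None if x_train.get("hf") is None else x_train["hf"][idx]
            ms = None if x_train.get("ms") is None else x_train["ms"][idx]
            z = model.forward(hf, ms, train=True)
            loss, dz = nn.bce_with_logits(z, y_train[idx])
            model.backward(dz)
            optimizer.step()
            losses.append(loss)

        probs = model.predict_proba(x_valid.get("hf"), x_valid.get("ms"))
        val_mcc = mcc_from_predictions(y_valid, (probs >= config.threshold).astype(int))
        history.append(EpochRecord(epoch, float(np.mean(losses)), val_mcc))
        if verbose:
            print(f"epoch {epoch:3d}  train_loss {np.mean(losses):.4f}  valid_mcc {val_mcc:+.4f}")

        if val_mcc > best_mcc:
            best_mcc = val_mcc
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.set_weights(best_weights)
    model.best_epoch = best_epoch
    model.best_valid_mcc = best_mcc
    return history


# --------------------------------------------------------------------------
# Encoding datasets for the classifier
# --------------------------------------------------------------------------


def encode_dataset(
    dataset: LabeledDataset,
    kernel: str = DEFAULT_KERNEL,
    scales=DEFAULT_SCALES,
    encoder: str = "edn",
) -> tuple[dict, np.ndarray]:
    """Batch-encode a fixed-length dataset into classifier inputs.

    ``encoder='edn'`` yields ``hf`` = the smallest-scale profile and
    ``ms`` = the full (4, S, N) stack; ``encoder='onehot'`` yields only
    ``hf`` = the indicator matrix (one-hot baseline input).
    """
    lengths = {len(s) for s in dataset.sequences}
    if len(lengths) != 1:
        raise EdnValidationError(f"batch encoding requires equal-length sequences, got lengths {sorted(lengths)}")
    if encoder == "edn":
        encs = [edn_multiscale(s, kernel, scales) for s in dataset.sequences]
        ms = np.stack([e.values for e in encs])
        hf = ms[:, :, 0, :]
        return {"hf": hf, "ms": ms}, dataset.labels
    if encoder == "onehot":
        from .baselines import one_hot_encode

        hf = np.stack([one_hot_encode(s).values for s in dataset.sequences])
        return {"hf": hf, "ms": None}, dataset.labels
    raise EdnValidationError(f"unknown encoder {encoder!r}; allowed: ['edn', 'onehot']")


# --------------------------------------------------------------------------
# Multi-run evaluation protocol
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-run test MCCs with their mean +/- sample sd."""

    per_run_mcc: list[float]
    mean: float
    sd: float
    n_runs: int
    config_digest: str = ""
    single_run: bool = False  # sd is 0 by convention when only one run

    @classmethod
    def from_runs(cls, mccs: list[float], config_digest: str = "") -> "EvalReport":
        mccs = [float(m) for m in mccs]
        n = len(mccs)
        mean = float(np.mean(mccs))
        sd = 0.0 if n < 2 else float(np.std(mccs, ddof=1))
        return cls(mccs, mean, sd, n, config_digest, single_run=(n == 1))

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class PipelineSpec:
    """Names everything one evaluation run needs."""

    encoder: str = "edn"  # 'edn' or 'onehot'
    kernel: str = DEFAULT_KERNEL
    scales: tuple[int, ...] = DEFAULT_SCALES
    selection: BranchSelection = field(default_factory=BranchSelection)
    model_config: ModelConfig = field(default_factory=ModelConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def digest(self) -> str:
        return hashlib.md5(repr(self).encode()).hexdigest()[:12]


def run_pipeline_once(
    pipeline: PipelineSpec,
    train: LabeledDataset,
    valid: LabeledDataset,
    test: LabeledDataset,
    seed: int,
) -> float:
    """Encode, train with early stopping, and return the test MCC."""
    enc = lambda ds: encode_dataset(ds, pipeline.kernel, pipeline.scales, pipeline.encoder)
    (x_tr, y_tr), (x_va, y_va), (x_te, y_te) = enc(train), enc(valid), enc(test)
    model = build_model(pipeline.model_config, pipeline.selection, seed=seed)
    cfg = replace(pipeline.train_config, seed=seed)
    train_with_early_stopping(model, (x_tr, y_tr), (x_va, y_va), cfg)
    probs = model.predict_proba(x_te.get("hf"), x_te.get("ms"))
    return mcc_from_predictions(y_te, (probs >= cfg.threshold).astype(int))


def evaluate_runs(
    pipeline: PipelineSpec,
    train: LabeledDataset,
    valid: LabeledDataset,
    test: LabeledDataset,
    seeds=(0, 1, 2, 3, 4),
) -> EvalReport:
    """Train/evaluate once per seed and aggregate mean +/- sd test MCC."""
    mccs = [run_pipeline_once(pipeline, train, valid, test, seed) for seed in seeds]
    return EvalReport.from_runs(mccs, config_digest=pipeline.digest())


# --------------------------------------------------------------------------
# Paired t-test
# --------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    n_pairs: int
    t_statistic: float | None
    p_value: float | None
    df: int
    mean_difference: float
    no_variance: bool = False


def paired_ttest(a, b) -> PairedTestResult:
    """Classical paired t-test on matched value lists (two-sided).

    Pairs are typically (dataset x run) MCC values of two methods.  If
    every difference is identical the result is flagged ``no_variance``
    and no statistic is reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EdnValidationError("paired test needs two equal-length 1-d value lists")
    n = a.size
    if n < 2:
        raise EdnValidationError("paired test needs at least two pairs")
    d = a - b
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        return PairedTestResult(n, None, None, n - 1, mean_d, no_variance=True)
    t = mean_d / (sd_d / math.sqrt(n))
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(n, float(t), float(p), n - 1, mean_d)
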