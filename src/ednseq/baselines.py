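"""Reference baselines: one-hot + HF-branch CNN, and k-mer frequencies
with gradient-boosted trees.

The one-hot baseline feeds the indicator encoding (rows A, C, G, T) to
the identical high-resolution convolutional branch and classifier under
the same training protocol, isolating what the density encoding itself
contributes.  The k-mer baseline summarizes each sequence as the 84
frequencies of all 1-, 2- and 3-mers and fits XGBoost (max depth 6,
fixed random state), a fully deterministic reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np

from .encoding import EdnValidationError, UNKNOWN_SYMBOL
from .data import LabeledDataset
from .model import BranchSelection
from .training import (
    EvalReport,
    PipelineSpec,
    TrainConfig,
    evaluate_runs,
    mcc_from_predictions,
)

__all__ = [
    "ONEHOT_BASE_ORDER",
    "KMER_NAMES",
    "OneHotMatrix",
    "one_hot_encode",
    "kmer_frequency_vector",
    "kmer_feature_matrix",
    "export_kmer_features_csv",
    "run_kmer_xgb_baseline",
    "run_onehot_hfbranch_baseline",
]

#: Alphabetical channel order of the one-hot encoding (A=[1,0,0,0]);
#: note the density encoding instead stacks channels as A, T, G, C.
ONEHOT_BASE_ORDER = ("A", "C", "G", "T")

#: All 84 k-mer feature names: 4 monomers, 16 dimers, 64 trimers,
#: each block lexicographic over A, C, G, T.
KMER_NAMES: tuple[str, ...] = tuple(
    "".join(p) for k in (1, 2, 3) for p in product("ACGT", repeat=k)
)
_KMER_INDEX = {name: i for i, name in enumerate(KMER_NAMES)}
_BLOCK_SLICES = {1: slice(0, 4), 2: slice(4, 20), 3: slice(20, 84)}


@dataclass
class OneHotMatrix:
    """4 x N binary indicator matrix, rows in order A, C, G, T."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 4:
            raise EdnValidationError(f"OneHotMatrix must be 4 x N, got {self.values.shape}")


def one_hot_encode(seq: str) -> OneHotMatrix:
    """Exact indicator matrix; unknown positions give all-zero columns."""
    mat = np.zeros((4, len(seq)))
    for row, base in enumerate(ONEHOT_BASE_ORDER):
        mat[row] = [1.0 if c == base else 0.0 for c in seq]
    return OneHotMatrix(mat)


def kmer_frequency_vector(seq: str) -> np.ndarray:
    """84-dim frequency vector over 1-, 2- and 3-mers.

    For each k the L-k+1 windows are counted and normalized by the
    number of counted windows; windows overlapping an unknown residue
    are skipped (and excluded from the normalizer).
    """
    if len(seq) < 3:
        raise EdnValidationError(f"k-mer features need length >= 3, got {len(seq)}")
    vec = np.zeros(len(KMER_NAMES))
    for k in (1, 2, 3):
        counted = 0
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if UNKNOWN_SYMBOL in window:
                continue
            vec[_KMER_INDEX[window]] += 1
            counted += 1
        if counted:
            vec[_BLOCK_SLICES[k]] /= counted
    return vec


def kmer_feature_matrix(dataset: LabeledDataset) -> np.ndarray:
    return np.stack([kmer_frequency_vector(s) for s in dataset.sequences])


def export_kmer_features_csv(dataset: LabeledDataset, path) -> None:
    """Feature matrix as CSV: 84 k-mer columns plus the label."""
    import pandas as pd

    df = pd.DataFrame(kmer_feature_matrix(dataset), columns=list(KMER_NAMES))
    df["label"] = dataset.labels
    df.to_csv(path, index=False)


def run_kmer_xgb_baseline(
    train: LabeledDataset,
    valid: LabeledDataset,
    test: LabeledDataset,
    max_depth: int = 6,
    seed: int = 42,
    n_estimators: int = 100,
    learning_rate: float = 0.3,
) -> EvalReport:
    """Gradient-boosted trees on k-mer frequencies; deterministic at a
    fixed seed (single-threaded, exact tree construction).

    Hyperparameters beyond depth and seed follow the library defaults
    and are recorded in the report digest.  The validation split is not
    consumed by the trees; it is kept in the signature so all baselines
    share one calling convention.
    """
    from xgboost import XGBClassifier

    if len(set(train.labels.tolist())) < 2:
        raise EdnValidationError("training set contains a single class")
    clf = XGBClassifier(
        max_depth=max_depth,
        random_state=seed,
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        n_jobs=1,
        tree_method="exact",
        eval_metric="logloss",
    )
    clf.fit(kmer_feature_matrix(train), train.labels)
    pred = clf.predict(kmer_feature_matrix(test))
    test_mcc = mcc_from_predictions(test.labels, pred)
    digest = f"kmer-xgb(depth={max_depth},seed={seed},rounds={n_estimators},lr={learning_rate})"
    return EvalReport.from_runs([test_mcc], config_digest=digest)


def run_onehot_hfbranch_baseline(
    train: LabeledDataset,
    valid: LabeledDataset,
    test: LabeledDataset,
    train_config: TrainConfig | None = None,
    seeds=(0, 1, 2, 3, 4),
) -> EvalReport:
    """One-hot encoding through the HF branch + classifier (~452 K
    parameters), trained with the standard protocol once per seed."""
    pipeline = PipelineSpec(
        encoder="onehot",
        selection=BranchSelection(use_hf=True, use_ms=False),
        train_config=train_config or TrainConfig(),
    )
    return evaluate_runs(pipeline, train, valid, test, seeds=seeds)
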