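"""Shared fixtures: independent density oracle and a cached end-to-end run."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# --------------------------------------------------------------------------
# Independent density oracle: pure-python double loop, scalar math only,
# no truncation.  Deliberately shares no code with the package encoder.
# --------------------------------------------------------------------------


def oracle_kernel(name: str, u: float) -> float:
    a = abs(u)
    if name == "gaussian":
        return math.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
    if name == "exponential":
        return 0.5 * math.exp(-a)
    if name == "linear":
        return 1.0 - a if a <= 1.0 else 0.0
    if name == "cosine":
        return (math.pi / 4.0) * math.cos(math.pi * u / 2.0) if a <= 1.0 else 0.0
    raise ValueError(name)


def oracle_edn_channel(seq: str, base: str, kernel: str, h: float) -> list[float]:
    positions = [i + 1 for i, c in enumerate(seq) if c == base]
    out = []
    for x in range(1, len(seq) + 1):
        total = 0.0
        for xi in positions:
            total += oracle_kernel(kernel, (x - xi) / h)
        out.append(total / h)
    return out


@pytest.fixture(scope="session")
def oracle():
    return oracle_edn_channel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng: np.random.Generator, length: int, with_unknown: bool = False) -> str:
    alphabet = list("ACGTN") if with_unknown else list("ACGT")
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_unknown else None
    return "".join(rng.choice(alphabet, size=length, p=p))


# --------------------------------------------------------------------------
# One full synthetic benchmark run, shared by the end-to-end tests.
# --------------------------------------------------------------------------


@pytest.fixture(scope="session")
def synth_splits():
    from ednseq import SyntheticSpec, generate_motif_dataset

    return generate_motif_dataset(
        SyntheticSpec(n_per_class=500, length=70, motif="TATAAA", seed=0)
    )


@pytest.fixture(scope="session")
def eden_synth_run(synth_splits):
    """Train the full dual-branch model once on the synthetic dataset.

    Ten-epoch cap keeps the run desk-scale; the task is separable so the
    validation MCC saturates well before that.
    """
    from ednseq import BranchSelection, ModelConfig, TrainConfig, build_model
    from ednseq.training import encode_dataset, mcc_from_predictions, train_with_early_stopping

    train, valid, test = synth_splits
    x_tr, y_tr = encode_dataset(train)
    x_va, y_va = encode_dataset(valid)
    x_te, y_te = encode_dataset(test)
    model = build_model(ModelConfig(), BranchSelection(True, True), seed=0)
    history = train_with_early_stopping(
        model, (x_tr, y_tr), (x_va, y_va), TrainConfig(max_epochs=10, patience=4, seed=0)
    )
    probs_test = model.predict_proba(x_te["hf"], x_te["ms"])
    probs_train = model.predict_proba(x_tr["hf"], x_tr["ms"])
    return {
        "model": model,
        "history": history,
        "test_mcc": mcc_from_predictions(y_te, (probs_test >= 0.5).astype(int)),
        "train_mcc": mcc_from_predictions(y_tr, (probs_train >= 0.5).astype(int)),
        "train_sequences": train.sequences,
        "train_labels": y_tr,
        "train_predictions": (probs_train >= 0.5).astype(int),
    }
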