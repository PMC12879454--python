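"""Datasets: CSV/FASTA readers and a synthetic motif-implant generator.

The labeled-CSV dialect is ``sequence,label`` with binary integer
labels, the format used by public genomic classification benchmarks
such as GUE (promoter / core-promoter / TF-binding tasks), so
downloaded benchmark files drop in unchanged.  The generator emulates
such binary tasks at desk scale: fixed-length background sequences with
configurable base composition, with one copy of a short motif implanted
at a uniformly random admissible offset in each positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EdnValidationError, canonicalize_sequence

__all__ = [
    "LabeledDataset",
    "SyntheticSpec",
    "read_sequence_csv",
    "write_sequence_csv",
    "read_fasta",
    "generate_motif_dataset",
]


@dataclass
class LabeledDataset:
    """Canonicalized sequences with binary labels and a named split."""

    records: list[tuple[str, int]]
    split_name: str = "train"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise EdnValidationError(f"dataset split {self.split_name!r} is empty")
        for i, (_, y) in enumerate(self.records):
            if y not in (0, 1):
                raise EdnValidationError(f"non-binary label {y!r} at record {i}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, y in self.records], dtype=int)


def read_sequence_csv(path, split_name: str = "train") -> LabeledDataset:
    """Read a ``sequence,label`` CSV; extra columns are tolerated."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EdnValidationError(f"{path}: empty file") from None
    missing = {"sequence", "label"} - set(df.columns)
    if missing:
        raise EdnValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise EdnValidationError(f"{path}: no data rows")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "label")
        try:
            y = int(raw)
        except (TypeError, ValueError):
            raise EdnValidationError(f"{path}: non-integer label {raw!r} at row {i + 2}") from None
        if y not in (0, 1):
            raise EdnValidationError(f"{path}: non-binary label {y!r} at row {i + 2}")
        records.append((canonicalize_sequence(str(getattr(row, "sequence"))), y))
    return LabeledDataset(records, split_name=split_name, provenance=str(path))


def write_sequence_csv(dataset: LabeledDataset, path) -> None:
    pd.DataFrame(dataset.records, columns=["sequence", "label"]).to_csv(path, index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (header id, canonicalized sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise EdnValidationError(
                        f"{path}: malformed FASTA — line {lineno} is not a header"
                    )
                break
        else:
            raise EdnValidationError(f"{path}: empty FASTA file")
    records = [(rec.id, canonicalize_sequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EdnValidationError(f"{path}: no FASTA records")
    return records


@dataclass
class SyntheticSpec:
    """Recipe for a binary motif-presence classification dataset.

    Defaults mirror a short TF-binding/promoter-style task: 70 nt
    sequences, uniform background, a single TATA-box-like hexamer in
    each positive.  Negatives are pure background and are not screened
    for chance motif hits; at the defaults that mislabeling pressure is
    (L - m + 1) * 4^-m ~= 1.6% of negatives.
    """

    n_per_class: int = 500
    length: int = 70
    motif: str = "TATAAA"
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self) -> None:
        self.motif = canonicalize_sequence(self.motif)
        if len(self.motif) > self.length:
            raise EdnValidationError(
                f"motif length {len(self.motif)} exceeds sequence length {self.length}"
            )
        if abs(sum(self.composition) - 1.0) > 1e-12:
            raise EdnValidationError("background composition must sum to 1")
        if self.n_per_class < 1:
            raise EdnValidationError("n_per_class must be >= 1")


_BASES = np.array(list("ACGT"))


def generate_motif_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Generate (train, validation, test) splits, 70/15/15 by default.

    Splits are stratified by label with floor rounding; the remainder
    goes to train.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, L, m = spec.n_per_class, spec.length, len(spec.motif)

    def background(count: int) -> list[str]:
        draws = rng.choice(_BASES, size=(count, L), p=list(spec.composition))
        return ["".join(row) for row in draws]

    negatives = [(s, 0) for s in background(n)]
    positives = []
    offsets = rng.integers(0, L - m + 1, size=n)
    for s, off in zip(background(n), offsets):
        positives.append((s[:off] + spec.motif + s[off + m :], 1))

    f_train, f_valid, f_test = spec.split_fractions
    n_valid, n_test = math.floor(n * f_valid), math.floor(n * f_test)
    n_train = n - n_valid - n_test

    def take(cls_records: list, a: int, b: int) -> list:
        return cls_records[a:b]

    prov = (
        f"synthetic motif dataset: n_per_class={n}, L={L}, motif={spec.motif}, "
        f"composition={spec.composition}, seed={spec.seed}"
    )
    splits = []
    bounds = [(0, n_train), (n_train, n_train + n_valid), (n_train + n_valid, n)]
    for name, (a, b) in zip(("train", "validation", "test"), bounds):
        recs = take(positives, a, b) + take(negatives, a, b)
        # deterministic interleave so labels are not block-ordered
        order = np.random.default_rng(spec.seed + 1).permutation(len(recs))
        recs = [recs[i] for i in order]
        splits.append(LabeledDataset(recs, split_name=name, provenance=prov))
    return tuple(splits)
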