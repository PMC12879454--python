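"""Hybrid dual-branch convolutional classifier over EDN encodings.

Two pathways read the encoded sequence: a high-resolution (HF) branch of
three same-padded 1-d convolutions over the single-base-scale profile
(4 x N), and a multiscale (MS) branch that applies two 2-d convolutions
across the (scale, position) plane of the stacked profile (4 x S x N),
collapses the scale axis by maximum, and finishes with a 1-d
convolution.  Each branch is adaptively max-pooled to a fixed length of
10, flattened to 128*10 = 1280 features, concatenated, and classified by
two dense layers (256 hidden units, one output logit squashed to a
probability).  With both branches the network has 1,069,697 trainable
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .encoding import EdnValidationError

__all__ = [
    "LayerSpec",
    "ModelConfig",
    "BranchSelection",
    "count_parameters",
    "build_model",
    "HybridClassifier",
    "predict_labels",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LayerSpec:
    """One parameterized layer with its closed-form parameter count."""

    layer_kind: str  # conv1d | conv2d | dense
    in_channels: int
    out_channels: int
    kernel_extent: int | tuple[int, int] | None = None
    has_bias: bool = True

    @property
    def param_count(self) -> int:
        bias = self.out_channels if self.has_bias else 0
        if self.layer_kind == "conv1d":
            return self.in_channels * self.out_channels * int(self.kernel_extent) + bias
        if self.layer_kind == "conv2d":
            kh, kw = self.kernel_extent
            return self.in_channels * self.out_channels * kh * kw + bias
        if self.layer_kind == "dense":
            return self.in_channels * self.out_channels + bias
        raise EdnValidationError(f"unknown layer kind {self.layer_kind!r}")


def _default_hf_branch() -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("conv1d", 4, 64, 5),
        LayerSpec("conv1d", 64, 128, 5),
        LayerSpec("conv1d", 128, 128, 5),
    )


def _default_ms_branch() -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("conv2d", 4, 64, (3, 3)),
        LayerSpec("conv2d", 64, 128, (5, 5)),
        LayerSpec("conv1d", 128, 128, 5),
    )


@dataclass
class ModelConfig:
    """Declarative architecture description.

    Defaults reproduce the reference dual-branch design: per-layer
    parameter counts 1,344 / 41,088 / 82,048 (HF), 2,368 / 204,928 /
    82,048 (MS), and a fusion stack of 655,616 + 257 when both branches
    feed the classifier.
    """

    hf_branch: tuple[LayerSpec, ...] = field(default_factory=_default_hf_branch)
    ms_branch: tuple[LayerSpec, ...] = field(default_factory=_default_ms_branch)
    pooled_length: int = 10
    fusion_hidden: int = 256
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.pooled_length < 1:
            raise EdnValidationError("pooled_length must be >= 1")

    def branch_feature_width(self) -> int:
        """Flattened features contributed by one branch (channels x pooled)."""
        return self.hf_branch[-1].out_channels * self.pooled_length

    def fusion_specs(self, selection: "BranchSelection") -> tuple[LayerSpec, LayerSpec]:
        width = self.branch_feature_width() * selection.n_branches
        return (
            LayerSpec("dense", width, self.fusion_hidden),
            LayerSpec("dense", self.fusion_hidden, 1),
        )

    def to_json(self, path) -> None:
        payload = {
            "hf_branch": [asdict(s) for s in self.hf_branch],
            "ms_branch": [asdict(s) for s in self.ms_branch],
            "pooled_length": self.pooled_length,
            "fusion_hidden": self.fusion_hidden,
            "dropout_rate": self.dropout_rate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelConfig":
        with open(path) as fh:
            payload = json.load(fh)

        def mk(d):
            ke = d.get("kernel_extent")
            if isinstance(ke, list):
                ke = tuple(ke)
            return LayerSpec(d["layer_kind"], d["in_channels"], d["out_channels"], ke, d.get("has_bias", True))

        return cls(
            hf_branch=tuple(mk(d) for d in payload["hf_branch"]),
            ms_branch=tuple(mk(d) for d in payload["ms_branch"]),
            pooled_length=payload["pooled_length"],
            fusion_hidden=payload["fusion_hidden"],
            dropout_rate=payload["dropout_rate"],
        )


@dataclass(frozen=True)
class BranchSelection:
    """Which branches feed the classifier (ablation setups)."""

    use_hf: bool = True
    use_ms: bool = True

    def __post_init__(self) -> None:
        if not (self.use_hf or self.use_ms):
            raise EdnValidationError("at least one branch must be enabled")

    @property
    def n_branches(self) -> int:
        return int(self.use_hf) + int(self.use_ms)


def count_parameters(config: ModelConfig, selection: BranchSelection = BranchSelection()) -> int:
    """Total trainable parameters from the closed-form layer formulas."""
    total = 0
    if selection.use_hf:
        total += sum(s.param_count for s in config.hf_branch)
    if selection.use_ms:
        total += sum(s.param_count for s in config.ms_branch)
    total += sum(s.param_count for s in config.fusion_specs(selection))
    return total


class HybridClassifier:
    """Trainable dual-branch network mapping EDN inputs to a probability.

    Inputs per sample: ``hf`` of shape (4, N) — the k = 1 profile — and
    ``ms`` of shape (4, S, N); either may be omitted when the matching
    branch is disabled.  The minimum supported sequence length is 4 when
    the HF branch is enabled (its two length-halving poolings must leave
    at least one position before adaptive pooling), else 1.
    """

    def __init__(self, config: ModelConfig, selection: BranchSelection = BranchSelection(), seed: int = 0):
        self.config = config
        self.selection = selection
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        d = config.dropout_rate

        self.hf = None
        self.ms = None
        if selection.use_hf:
            c1, c2, c3 = config.hf_branch
            self.hf = nn.Sequential(
                nn.Conv1d(c1.in_channels, c1.out_channels, c1.kernel_extent, rng),
                nn.ReLU(),
                nn.MaxPool1d(),
                nn.Dropout(d),
                nn.Conv1d(c2.in_channels, c2.out_channels, c2.kernel_extent, rng),
                nn.ReLU(),
                nn.MaxPool1d(),
                nn.Dropout(d),
                nn.Conv1d(c3.in_channels, c3.out_channels, c3.kernel_extent, rng),
                nn.ReLU(),
                nn.AdaptiveMaxPool1d(config.pooled_length),
                nn.Flatten(),
            )
        if selection.use_ms:
            m1, m2, m3 = config.ms_branch
            self.ms = nn.Sequential(
                nn.Conv2d(m1.in_channels, m1.out_channels, m1.kernel_extent, rng),
                nn.ReLU(),
                nn.Conv2d(m2.in_channels, m2.out_channels, m2.kernel_extent, rng),
                nn.ReLU(),
                nn.MaxOverAxis(axis=2),
                nn.Conv1d(m3.in_channels, m3.out_channels, m3.kernel_extent, rng),
                nn.ReLU(),
                nn.AdaptiveMaxPool1d(config.pooled_length),
                nn.Flatten(),
            )
        f1, f2 = config.fusion_specs(selection)
        self.head = nn.Sequential(
            nn.Dense(f1.in_channels, f1.out_channels, rng),
            nn.ReLU(),
            nn.Dense(f2.in_channels, f2.out_channels, rng),
        )
        # training-time RNG (dropout masks); reseeded by the train loop
        self._rng = np.random.default_rng(self.seed + 1)

    # -- plumbing ----------------------------------------------------------

    @property
    def min_length(self) -> int:
        return 4 if self.selection.use_hf else 1

    def _check_length(self, n: int) -> None:
        if n < self.min_length:
            raise EdnValidationError(
                f"sequence length {n} too short for the convolution/pooling stack; "
                f"minimum supported length is {self.min_length}"
            )

    def modules(self) -> dict[str, nn.Layer]:
        out: dict[str, nn.Layer] = {}
        for branch_name, branch in (("hf", self.hf), ("ms", self.ms), ("head", self.head)):
            if branch is None:
                continue
            for li, layer in enumerate(branch.layers):
                if layer.params:
                    out[f"{branch_name}.{li}"] = layer
        return out

    def param_count(self) -> int:
        return sum(m.param_count() for m in self.modules().values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{k}/{n}": p.copy() for k, m in self.modules().items() for n, p in m.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, m in self.modules().items():
            for n in m.params:
                m.params[n][...] = weights[f"{k}/{n}"]

    # -- forward / backward ------------------------------------------------

    def forward(self, hf: np.ndarray | None, ms: np.ndarray | None, *, train: bool = False) -> np.ndarray:
        """Logits for a batch; ``hf`` (B,4,N), ``ms`` (B,4,S,N)."""
        feats = []
        if self.hf is not None:
            if hf is None:
                raise EdnValidationError("HF branch enabled but no hf input given")
            self._check_length(hf.shape[-1])
            feats.append(self.hf.forward(np.asarray(hf, dtype=float), train=train, rng=self._rng))
        if self.ms is not None:
            if ms is None:
                raise EdnValidationError("MS branch enabled but no ms input given")
            feats.append(self.ms.forward(np.asarray(ms, dtype=float), train=train, rng=self._rng))
        self._split = [f.shape[1] for f in feats]
        fused = np.concatenate(feats, axis=1)
        return self.head.forward(fused, train=train, rng=self._rng)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits[:, None])
        chunks = np.split(dfused, np.cumsum(self._split)[:-1], axis=1)
        it = iter(chunks)
        if self.hf is not None:
            self.hf.backward(next(it))
        if self.ms is not None:
            self.ms.backward(next(it))

    def predict_proba(self, hf: np.ndarray | None, ms: np.ndarray | None, batch_size: int = 64) -> np.ndarray:
        """Probabilities in (0,1), evaluation mode (dropout off)."""
        n = (hf if hf is not None else ms).shape[0]
        out = np.empty(n)
        for s in range(0, n, batch_size):
            z = self.forward(
                None if hf is None else hf[s : s + batch_size],
                None if ms is None else ms[s : s + batch_size],
                train=False,
            )
            out[s : s + batch_size] = nn.sigmoid(z)
        return out


def build_model(
    config: ModelConfig | None = None,
    selection: BranchSelection = BranchSelection(),
    seed: int = 0,
) -> HybridClassifier:
    """Construct the classifier; defaults give the full dual-branch network."""
    return HybridClassifier(config or ModelConfig(), selection, seed=seed)


def predict_labels(model: HybridClassifier, batch: dict, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 where predicted probability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise EdnValidationError(f"threshold must lie in [0, 1], got {threshold}")
    probs = model.predict_proba(batch.get("hf"), batch.get("ms"))
    return (probs >= threshold).astype(int)


def save_checkpoint(model: HybridClassifier, path, *, epoch: int | None = None, extra: dict | None = None) -> None:
    """Weights plus config/seed/epoch metadata in one .npz archive."""
    meta = {
        "seed": model.seed,
        "epoch": epoch,
        "selection": {"use_hf": model.selection.use_hf, "use_ms": model.selection.use_ms},
        "config": {
            "pooled_length": model.config.pooled_length,
            "fusion_hidden": model.config.fusion_hidden,
            "dropout_rate": model.config.dropout_rate,
        },
        **(extra or {}),
    }
    np.savez(path, __meta__=json.dumps(meta), **model.get_weights())


def load_checkpoint(path, config: ModelConfig | None = None) -> tuple[HybridClassifier, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    selection = BranchSelection(**meta["selection"])
    model = HybridClassifier(config or ModelConfig(), selection, seed=meta["seed"])
    model.set_weights({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
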