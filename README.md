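# ednseq

Multiscale kernel-density encoding of DNA sequences — the **EDN**
(Expected Density of Nucleotide) representation — with the hybrid
dual-branch convolutional classifier that consumes it, two reference
baselines, and the training/evaluation protocol used to compare them.

## The problem and the idea

Classifiers for regulatory genomics (promoter detection, transcription
factor binding prediction) need a numerical view of a symbolic sequence.
One-hot encoding keeps exact positions but carries no context; k-mer
frequency vectors capture composition but discard position. EDN bridges
the two: for each base Z ∈ {A, C, G, T}, kernel density estimation over
the positions x_i at which Z occurs yields a smooth per-position track

    EDN_Z(x) = N_Z · f̂_Z(x) = (1/h) Σ_i K((x − x_i)/h),   x = 1 … N,

evaluated only at the integer nucleotide positions. The bandwidth *h*
sets the spatial scale: at the 1-mer scale the linear (triangular)
kernel reproduces one-hot encoding exactly; at wider bandwidths the
track measures local base-richness without losing position. Bandwidths
are calibrated per kernel so that K decays to exactly 50% of its
central maximum at the k-mer window boundary b = k/2 (closed forms:
gaussian h = b/√(2 ln 2), exponential h = b/ln 2, linear h = 2b, cosine
h = 3b/2). Stacking the scales k = 1, 3, 5, 7 gives a (4 × 4 × N)
multiscale array; for clean sequences the four channel densities sum to
1 at interior positions.

Two convolutional branches read the encoding — a high-resolution branch
on the k = 1 slice and a multiscale branch applying 2-d convolutions
across the (scale, position) plane — and are fused by two dense layers
into one probability (1,069,697 trainable parameters in total). The
small network is implemented directly on NumPy (`ednseq.nn`) with
analytic backprop and Adam. Baselines: the identical high-resolution
branch on one-hot input (452,673 parameters), and 84-dimensional
1–3-mer frequency vectors with gradient-boosted trees.

## Worked example

```python
import ednseq as E

# densities of the worked 15-mer
ms = E.edn_multiscale("TCTGCTATGGCTAAT", kernel="cosine", scales=(1, 3, 5, 7))
print(ms.values.shape)                    # (4, 4, 15)
print(round(ms.values[1, 1, 0], 5))       # T channel, k=3 scale, position 1 -> 0.40968
print(round(E.calibrate_bandwidth("cosine", 3), 2))  # 2.25

# a synthetic motif task, end to end
from ednseq import SyntheticSpec, generate_motif_dataset, run_kmer_xgb_baseline
train, valid, test = generate_motif_dataset(
    SyntheticSpec(n_per_class=500, length=70, motif="TATAAA", seed=0))
report = run_kmer_xgb_baseline(train, valid, test, seed=42)
print(round(report.mean, 3))              # 0.843
```

The T-channel density at position 1 is 0.40968: only the T's at
positions 1 and 3 fall inside the cosine kernel's support at h = 2.25,
so the value is (K(0) + K(2/2.25))/2.25. The boosted-tree baseline
reaches test MCC ≈ 0.84 on the held-out split because the implanted
TATAAA motif shifts the 3-mer frequencies; the trained dual-branch
model reaches ≈ 0.99 (see `tests/test_acceptance.py`).

The same workflows are available from the shell:

```bash
ednseq synth --n-per-class 500 --length 70 --motif TATAAA --seed 0 --out-dir data/
ednseq encode data/train.csv --kernel cosine --out data/train.h5
ednseq calibrate --out-dir calib/
ednseq evaluate --train data/train.csv --valid data/validation.csv \
    --test data/test.csv --seeds 0,1,2,3,4 --out eden.json
ednseq baseline --kind kmer-xgb --train data/train.csv --valid data/validation.csv \
    --test data/test.csv --out xgb.json
```

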