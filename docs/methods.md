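# Methods

## The EDN representation

A canonicalized DNA sequence (uppercase; U→T; anything else becomes the
unknown symbol N, which belongs to no channel but still occupies a
position) is encoded per base Z ∈ {A, T, G, C} as

    EDN_Z(x) = (1/h) Σ_i K((x − x_i)/h),  x = 1 … N (1-based),

with x_i the positions of Z. The four tracks are stacked in channel
order A, T, G, C. Densities are evaluated only at integer sequence
positions, never between them, and no edge correction is applied near
the sequence ends.

**Kernels.** Four integral-normalized, even, unimodal families:
gaussian (2π)^{-1/2}e^{-u²/2}, exponential ½e^{-|u|}, linear
(triangular) 1−|u| on |u| ≤ 1, cosine (π/4)cos(πu/2) on |u| ≤ 1.
Because the bandwidth calibration below is a *ratio* criterion, the
normalization constant cancels there, while integral normalization is
what makes the interior channel sums equal 1.

**Bandwidth calibration.** For a k-mer window centered on a position
the boundary sits at offset b = k/2. The bandwidth is chosen so the
kernel magnitude at the boundary is exactly half its central maximum,
K(b/h) = K(0)/2, giving closed forms h = b/√(2 ln 2) (gaussian),
b/ln 2 (exponential), 2b (linear), 3b/2 (cosine). Default scales are
k = 1, 3, 5, 7 — single-base identity, codon/motif-core context,
binding-site extent, and domain-scale composition. The default kernel
is cosine; both are configuration choices, not constants.

**Computation.** The encoder convolves each base-indicator track with
the kernel sampled at integer offsets and scaled by 1/h. The stencil
length is fixed by (kernel, h), so the cost is O(N) per sequence with
work per position bounded by the kernel support. Unbounded kernels are
truncated at 9h (gaussian) and 26h (exponential); those radii keep the
dropped tail below 1e-10 per density value — the tighter exponential
radius matters because its tail decays only geometrically in the tap
index. All densities are double precision. Tests compare the encoder
against an untruncated pure-Python double-loop oracle at 1e-9.

**Properties asserted by the suite.** Linear kernel at k = 1 is exactly
one-hot (up to the A,C,G,T vs A,T,G,C row permutation of the one-hot
baseline); reversal symmetry; translation equivariance of interior
columns; interior four-channel sums equal 1 exactly for the linear
kernel at every default scale and deviate by a discretization error
bounded by 0.16 at k = 1 shrinking to 0.01 at k = 7 for the others (the
Riemann sum over unit-spaced offsets approaches the unit integral as h
grows).

## The classifier

Two branches read the encoding:

- **High-resolution (HF) branch**, input (4, N), the k = 1 slice:
  conv1d 4→64 (k5) → ReLU → maxpool/2 → dropout 0.2 → conv1d 64→128
  (k5) → ReLU → maxpool/2 → dropout 0.2 → conv1d 128→128 (k5) → ReLU.
- **Multiscale (MS) branch**, input (4, S, N): conv2d 4→64 (3×3) →
  ReLU → conv2d 64→128 (5×5) → ReLU → max over the scale axis →
  conv1d 128→128 (k5) → ReLU.

All convolutions are same-padded (on both the scale and position axes),
so length bookkeeping is driven by pooling alone. Each branch ends with
adaptive max pooling to length 10 and flattening (128·10 = 1280
features); the concatenation feeds dense 2560→256 → ReLU → dense
256→1, squashed to a probability by the logistic function. Totals:
1,069,697 parameters with both branches, 452,673 HF-only, 617,537
MS-only; per-layer counts are computed in closed form
(in·out·k + out etc.) and verified against introspection of the built
network.

Design points that were genuinely open: pooling placement (after the
first two HF convolutions only, so 70-nt inputs keep ≥ 10 positions
before adaptive pooling; minimum supported length 4), the 2-d→1-d
transition in the MS branch (same-padding preserves all scales through
both 2-d layers; collapse by maximum yields the 128-channel 1-d
stream), dropout only in the HF pooled blocks, and Kaiming-uniform
initialization (fan-in bound), the conventional default for
ReLU networks. Other geometries reproduce the same parameter counts;
these choices are recorded here rather than implied to be forced.

The engine (`ednseq.nn`) carries no batch-coupled state (no batch
normalization), so outputs are invariant to batch composition; adaptive
pooling makes the network length-agnostic above the minimum.

## Training and evaluation protocol

Binary cross-entropy on the logit, Adam (lr 1e-3, β = 0.9/0.999),
batch size 32. After each epoch the validation MCC at threshold 0.5 is
computed; training stops after `patience` (default 4) consecutive
epochs without a *strictly* greater validation MCC, or at `max_epochs`,
and the best-epoch weights are restored. The run seed controls weight
initialization, batch order, and dropout masks; runs are bitwise
reproducible.

MCC is computed from the closed form
(tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)), defined as 0 when a
denominator factor vanishes; it is cross-checked against scikit-learn.
The evaluation protocol trains once per seed (0–4 by convention) and
reports mean ± sample standard deviation (n−1). Methods are compared
with a classical two-sided paired t-test on matched (dataset × run)
MCC values; the statistic is the hand formula mean(d)/(sd(d)/√n) with
n−1 degrees of freedom (p-value from the t distribution), cross-checked
against scipy's paired test; identical pairs yield a flagged
no-variance result instead of a statistic.

**Baselines.** (i) One-hot (rows A, C, G, T) through the identical HF
branch and classifier, same protocol. (ii) 84-dimensional 1–3-mer
frequency vectors (each k-block normalized by its counted windows;
windows overlapping unknowns skipped) with XGBoost, max depth 6,
random state 42, single-threaded exact tree construction — fully
deterministic; remaining hyperparameters are the library defaults
(100 rounds, learning rate 0.3), recorded in the report digest.

## Synthetic data

`generate_motif_dataset` emulates a binary regulatory-sequence task:
background sequences drawn i.i.d. from a configurable composition
(uniform by default), length 70, 500 per class, with one copy of the
motif (default TATAAA, a TATA-box consensus) implanted at a uniform
random offset in each positive; 70/15/15 stratified splits (floor
rounding, remainder to train), fully reproducible from the seed.
Negatives are not screened for chance motif hits, leaving label noise
of about (L−m+1)·4^{−m} ≈ 1.6% of negatives — deliberate, for realism.

What this does *not* emulate: positional preference of real motifs,
degenerate/fuzzy motif instances, composition gradients (CpG islands),
length variation, or class imbalance. Passing end-to-end tests
therefore shows the pipeline learns a planted positional signal under
label noise, not that it matches benchmark MCCs on real promoter or
TF-binding data; those require the external GUE benchmark and are
covered by the optional extended tests, which run only when a local
copy of the data is present.

## Problem sizes and numerical choices

End-to-end runs train on the 500/class synthetic task with a 10-epoch
cap: the task is separable and validation MCC saturates (≥ 0.95)
within the cap, which keeps a full dual-branch fit to a few minutes on
one CPU core. Kernel calibration is exact closed-form and tested to
1e-9 against bisection; encoder-vs-oracle agreement is asserted at
1e-9; checkpoint round-trips are exact. Degenerate inputs are rejected
with validation errors: empty sequences, even or non-positive k,
non-increasing scale sets, h ≤ 0, sequences shorter than 4 for the HF
stack, single-class training sets, non-binary labels, all-zero
confusion matrices.

## Known limitations

- Bandwidths are fixed by the half-maximum rule; no adaptive or learned
  scales.
- Densities are evaluated only at integer positions; no base-resolution
  output.
- The NumPy engine targets this architecture; it supports exactly the
  layers the model needs and trains on CPU only.
- Batch encoding for the classifier requires equal-length sequences
  (the benchmark setting); variable-length corpora must be grouped or
  padded by the caller.
- The XGBoost baseline's determinism claim holds for the single-threaded
  exact-method configuration used here.
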