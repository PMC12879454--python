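"""Kernels, bandwidth calibration, and EDN density profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

import ednseq as E
from ednseq.encoding import EdnValidationError, KERNELS

from conftest import random_dna

KERNEL_NAMES = ("cosine", "linear", "exponential", "gaussian")
SCALES = (1, 3, 5, 7)

FIG_SEQ = "TCTGCTATGGCTAAT"

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


# --------------------------------------------------------------------------
# Kernel profiles
# --------------------------------------------------------------------------


@pytest.mark.parametrize("kernel", KERNEL_NAMES)
def test_kernel_integrates_to_one(kernel):
    val, _ = quad(lambda u: E.kernel_value(kernel, u), -50, 50, limit=500)
    assert abs(val - 1.0) < 1e-9


@pytest.mark.parametrize("kernel", KERNEL_NAMES)
def test_kernel_even_nonnegative_maximal_at_zero(kernel):
    u = np.linspace(-6, 6, 241)
    vals = E.kernel_value(kernel, u)
    assert np.allclose(vals, vals[::-1])
    assert (vals >= 0).all()
    assert E.kernel_value(kernel, 0.0) == pytest.approx(vals.max())


@pytest.mark.parametrize(
    "kernel, u, expected",
    [
        ("gaussian", 0.0, 1.0 / math.sqrt(2 * math.pi)),
        ("linear", 0.5, 0.5),
        ("cosine", 1.2, 0.0),
        ("exponential", 0.0, 0.5),
        ("cosine", 0.0, math.pi / 4),
    ],
)
def test_kernel_closed_form_values(kernel, u, expected):
    assert E.kernel_value(kernel, u) == pytest.approx(expected, abs=1e-9)


def test_unknown_kernel_names_allowed_set():
    with pytest.raises(EdnValidationError, match="cosine"):
        E.kernel_value("epanechnikov", 0.0)


# --------------------------------------------------------------------------
# Bandwidth calibration
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kernel, k, expected",
    [
        ("linear", 1, 1.0),
        ("gaussian", 3, 1.5 / math.sqrt(2 * math.log(2))),
        ("cosine", 7, 5.25),
        ("exponential", 5, 2.5 / math.log(2)),
    ],
)
def test_calibration_closed_forms(kernel, k, expected):
    assert E.calibrate_bandwidth(kernel, k) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("kernel", KERNEL_NAMES)
@pytest.mark.parametrize("k", SCALES)
def test_calibration_agrees_with_root_finding(kernel, k):
    """h solving K(b/h)/K(0) = 1/2 by bisection matches the closed form."""
    b = k / 2.0
    k0 = E.kernel_value(kernel, 0.0)
    f = lambda h: E.kernel_value(kernel, b / h) / k0 - 0.5
    h_root = brentq(f, 1e-6, 50.0, xtol=1e-12)
    assert E.calibrate_bandwidth(kernel, k) == pytest.approx(h_root, abs=1e-9)


def test_bandwidth_increases_with_scale():
    for kernel in KERNEL_NAMES:
        hs = [E.calibrate_bandwidth(kernel, k) for k in SCALES]
        assert all(b > a for a, b in zip(hs, hs[1:]))


@pytest.mark.parametrize("bad_k", [0, -3, 2, 4])
def test_calibration_rejects_even_or_nonpositive_k(bad_k):
    with pytest.raises(EdnValidationError):
        E.calibrate_bandwidth("cosine", bad_k)


def test_bandwidth_table_covers_all_pairs():
    table = E.bandwidth_table()
    assert len(table) == 16
    for (kernel, k), h in table.items():
        ratio = E.kernel_value(kernel, (k / 2) / h) / E.kernel_value(kernel, 0.0)
        assert ratio == pytest.approx(0.5, abs=1e-9)


# --------------------------------------------------------------------------
# Canonicalization and channel extraction
# --------------------------------------------------------------------------


def test_canonicalization_rules():
    assert E.canonicalize_sequence("acgu") == "ACGT"
    assert E.canonicalize_sequence("ACRYT") == "ACNNT"
    with pytest.raises(EdnValidationError):
        E.canonicalize_sequence("")


@pytest.mark.parametrize(
    "seq, base, positions",
    [
        ("ACGT", "A", (1,)),
        (FIG_SEQ, "T", (1, 3, 6, 8, 12, 15)),
        ("AAAA", "G", ()),
    ],
)
def test_channel_positions(seq, base, positions):
    cp = E.extract_channel_positions(seq, base)
    assert cp.positions == positions
    assert cp.count == len(positions)


def test_channel_counts_partition_clean_sequence(rng):
    seq = random_dna(rng, 60)
    counts = sum(E.extract_channel_positions(seq, b).count for b in "ACGT")
    assert counts == len(seq)
    seq_n = E.canonicalize_sequence(seq[:30] + "N" + seq[30:])
    counts_n = sum(E.extract_channel_positions(seq_n, b).count for b in "ACGT")
    assert counts_n == len(seq_n) - 1


# --------------------------------------------------------------------------
# Density evaluation
# --------------------------------------------------------------------------


def test_linear_kernel_unit_bandwidth_gives_indicator():
    assert np.allclose(E.edn_channel("ACGT", "A", "linear", 1.0), [1, 0, 0, 0])


def test_interior_triangular_sum_telescopes_to_one():
    seq = "A" * 200
    vals = E.edn_channel(seq, "A", "linear", 3.0)
    assert vals[99] == pytest.approx(1.0, abs=1e-12)


def test_fig_sequence_spot_value_matches_oracle(oracle):
    h = E.calibrate_bandwidth("cosine", 3)
    assert h == pytest.approx(2.25)
    got = E.edn_channel(FIG_SEQ, "T", "cosine", h)
    assert got[0] == pytest.approx(0.40968, abs=5e-6)
    assert got[0] == pytest.approx(oracle(FIG_SEQ, "T", "cosine", h)[0], abs=1e-12)


def test_nonpositive_bandwidth_rejected():
    with pytest.raises(EdnValidationError):
        E.edn_channel("ACGT", "A", "linear", 0.0)


def test_single_scale_identity_profile():
    prof = E.edn_single_scale("ACGT", "linear", 1)
    expected = {"A": [1, 0, 0, 0], "T": [0, 0, 0, 1], "G": [0, 0, 1, 0], "C": [0, 1, 0, 0]}
    for row, base in enumerate(E.EDN_BASE_ORDER):
        assert np.allclose(prof.values[row], expected[base])
    assert prof.bandwidth == 1.0 and prof.scale_k == 1


def test_single_scale_shape_and_metadata(rng):
    prof = E.edn_single_scale(random_dna(rng, 15), "cosine", 3)
    assert prof.values.shape == (4, 15)
    assert prof.kernel == "cosine"


def test_gaussian_interior_column_sum_near_one(rng):
    seq = random_dna(rng, 200)
    prof = E.edn_single_scale(seq, "gaussian", 7)
    assert prof.values[:, 99].sum() == pytest.approx(1.0, abs=1e-6)


def test_absent_base_row_is_zero():
    prof = E.edn_single_scale("AAAA", "gaussian", 3)
    g_row = list(E.EDN_BASE_ORDER).index("G")
    assert np.all(prof.values[g_row] == 0.0)
    assert np.all(prof.values >= 0) and np.all(np.isfinite(prof.values))


def test_multiscale_stacks_single_scales(rng):
    seq = random_dna(rng, 15)
    ms = E.edn_multiscale(seq, "cosine", (1, 3, 5, 7))
    assert ms.values.shape == (4, 4, 15)
    for si, k in enumerate((1, 3, 5, 7)):
        single = E.edn_single_scale(seq, "cosine", k)
        assert np.array_equal(ms.values[:, si, :], single.values)


def test_multiscale_rejects_bad_scale_sets():
    with pytest.raises(EdnValidationError):
        E.edn_multiscale("ACGT", "cosine", ())
    with pytest.raises(EdnValidationError):
        E.edn_multiscale("ACGT", "cosine", (3, 1))
    with pytest.raises(EdnValidationError):
        E.edn_multiscale("ACGT", "cosine", (1, 2))


# --------------------------------------------------------------------------
# Invariants
# --------------------------------------------------------------------------


@pytest.mark.parametrize("kernel", KERNEL_NAMES)
@pytest.mark.parametrize("k", SCALES)
def test_encoder_matches_naive_oracle(kernel, k, oracle, rng):
    """Vectorized encoder vs untruncated double-loop summation, 1e-9."""
    h = E.calibrate_bandwidth(kernel, k)
    for _ in range(8):
        seq = random_dna(rng, int(rng.integers(3, 51)), with_unknown=True)
        seq = E.canonicalize_sequence(seq)
        for base in "ACGT":
            got = E.edn_channel(seq, base, kernel, h)
            assert np.max(np.abs(got - np.array(oracle(seq, base, kernel, h)))) < 1e-9


@given(seq=dna)
def test_one_hot_limit_property(seq):
    """Linear kernel at k = 1 is the exact 0/1 indicator encoding."""
    prof = E.edn_single_scale(seq, "linear", 1)
    for row, base in enumerate(E.EDN_BASE_ORDER):
        indicator = np.array([1.0 if c == base else 0.0 for c in seq])
        assert np.array_equal(prof.values[row], indicator)


@given(seq=dna, kernel=st.sampled_from(KERNEL_NAMES), k=st.sampled_from(SCALES))
def test_reversal_symmetry(seq, kernel, k):
    fwd = E.edn_single_scale(seq, kernel, k).values
    rev = E.edn_single_scale(seq[::-1], kernel, k).values
    assert np.allclose(fwd, rev[:, ::-1], atol=1e-12)


def test_translation_locality():
    """Implanting a motif d positions later shifts interior columns by d."""
    motif = "GGGCCC"
    background = "A" * 120
    k, kernel = 5, "cosine"

    def embed(offset):
        s = background[:offset] + motif + background[offset + len(motif) :]
        return E.edn_single_scale(s, kernel, k).values

    a, b, d = embed(40), embed(47), 7
    # compare columns well inside the sequence, away from both ends
    assert np.allclose(a[:, 30:60], b[:, 30 + d : 60 + d], atol=1e-9)


@pytest.mark.parametrize("kernel", KERNEL_NAMES)
def test_interior_normalization_bounds(kernel, rng):
    """Interior four-channel sums: exact for linear, bounded discretization
    error otherwise (< 0.16 at k = 1 shrinking to < 0.01 at k = 7)."""
    seq = random_dna(rng, 160)
    bounds = {1: 0.16, 3: 0.08, 5: 0.02, 7: 0.01}
    for k, bound in bounds.items():
        ms = E.edn_single_scale(seq, kernel, k)
        interior = ms.values[:, 60:100].sum(axis=0)
        dev = np.max(np.abs(interior - 1.0))
        if kernel == "linear":
            assert dev < 1e-9
        else:
            assert dev < bound


def test_work_per_position_is_bounded():
    """O(N) contract: the tap stencil length is fixed by (kernel, h),
    independent of sequence length."""
    from ednseq.encoding import KERNELS, _kernel_taps

    for kernel in KERNEL_NAMES:
        h = E.calibrate_bandwidth(kernel, 7)
        taps = _kernel_taps(KERNELS[kernel], h)
        radius = KERNELS[kernel].support_radius or KERNELS[kernel].truncation_radius
        assert len(taps) <= 2 * math.ceil(radius * h) + 1


@pytest.mark.parametrize("kernel", ["gaussian", "exponential"])
def test_truncation_error_below_1e9(kernel, oracle):
    """Cutting unbounded kernels at the truncation radius changes no
    density value by more than 1e-9 (checked against the full sum)."""
    seq = "A" * 300
    h = E.calibrate_bandwidth(kernel, 7)
    got = E.edn_channel(seq, "A", kernel, h)
    ref = np.array(oracle(seq, "A", kernel, h))
    assert np.max(np.abs(got - ref)) < 1e-9


# --------------------------------------------------------------------------
# Container I/O and calibration report
# --------------------------------------------------------------------------


def test_hdf5_roundtrip(tmp_path, rng):
    seqs = [random_dna(rng, 20) for _ in range(3)]
    encs = [E.edn_multiscale(s, "cosine") for s in seqs]
    path = tmp_path / "enc.h5"
    E.write_encoded_hdf5(path, encs, ids=[f"s{i}" for i in range(3)])
    ids, back = E.read_encoded_hdf5(path)
    assert ids == ["s0", "s1", "s2"]
    for orig, loaded in zip(encs, back):
        assert np.array_equal(orig.values, loaded.values)
        assert loaded.scales == (1, 3, 5, 7)
        assert loaded.bandwidths == pytest.approx([E.calibrate_bandwidth("cosine", k) for k in (1, 3, 5, 7)])


def test_calibration_report(tmp_path):
    E.write_calibration_report(tmp_path)
    import pandas as pd

    table = pd.read_csv(tmp_path / "bandwidth_calibration.csv")
    assert len(table) == 16
    assert np.allclose(table["boundary_ratio"], 0.5, atol=1e-9)
    assert table.loc[(table.kernel == "linear") & (table.k == 1), "bandwidth_h"].item() == 1.0
    curves = pd.read_csv(tmp_path / "kernel_curves.csv")
    assert set(curves.kernel) == set(KERNEL_NAMES)
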