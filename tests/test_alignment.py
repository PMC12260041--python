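"""Partitioning, RBF kernel, median bandwidth and the MMD^2 estimator."""

import numpy as np
import pytest

from udil.alignment import (
    KernelConfig,
    Partition,
    alignment_loss,
    alignment_loss_grad,
    median_bandwidth,
    mmd2,
    mmd2_grad,
    partition_samples,
    rbf_kernel,
)
from udil.synthetic import NEGATIVE_LABEL, POSITIVE_LABEL
from udil.thresholds import ClassThresholds, DivergenceRecord


def thr(tau_m, tau_h):
    return ClassThresholds(mu_m=tau_m, sigma_m=0, sens_m=0, tau_m=tau_m,
                           mu_h=tau_h, sigma_h=0, sens_h=0, tau_h=tau_h)


def rec(idx, label, div, reliable=True):
    return DivergenceRecord(sample_index=idx, label=label, divergence=div,
                            uncertainty_current=0.2, reliable=reliable)


def test_partition_forced_index_sets():
    records = [rec(i, POSITIVE_LABEL, d) for i, d in enumerate([0.05, 0.2, 0.1, 0.4])]
    part = partition_samples(records, thr(0.15, 0.15))
    assert part.similar_m.tolist() == [0, 2]
    assert part.dissimilar_m.tolist() == [1, 3]


def test_partition_low_threshold_empties_similar():
    records = [rec(i, NEGATIVE_LABEL, d) for i, d in enumerate([0.3, 0.4])]
    part = partition_samples(records, thr(0.0, 0.0))
    assert part.similar_h.size == 0
    assert part.dissimilar_h.tolist() == [0, 1]


def test_partition_reliability_gate():
    records = [rec(0, POSITIVE_LABEL, 0.01, reliable=False),
               rec(1, POSITIVE_LABEL, 0.01, reliable=True)]
    part = partition_samples(records, thr(0.5, 0.5))
    assert part.similar_m.tolist() == [1]
    assert part.dissimilar_m.tolist() == [0]


def test_partition_exhaustive_and_disjoint():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, 30)
    records = [rec(i, labels[i], float(rng.uniform(0, 1))) for i in range(30)]
    part = partition_samples(records, thr(0.5, 0.3))
    joined = np.sort(np.concatenate([part.similar_all, part.dissimilar_all]))
    assert joined.tolist() == list(range(30))
    assert np.intersect1d(part.similar_all, part.dissimilar_all).size == 0


def test_rbf_kernel_values_and_oracle():
    assert rbf_kernel(np.zeros((1, 3)), np.zeros((1, 3)), 2.0)[0, 0] == 1.0
    a = np.array([[0.0, 0.0]])
    b = np.array([[2.0, 0.0]])  # ||a-b||^2 = 4 = 2 sigma^2 with sigma = sqrt 2
    assert rbf_kernel(a, b, np.sqrt(2.0))[0, 0] == pytest.approx(np.exp(-1.0))
    rng = np.random.default_rng(1)
    x, y = rng.standard_normal((5, 3)), rng.standard_normal((4, 3))
    k = rbf_kernel(x, y, 1.3)
    for i in range(5):
        for j in range(4):
            expected = np.exp(-np.sum((x[i] - y[j]) ** 2) / (2 * 1.3**2))
            assert k[i, j] == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        rbf_kernel(x, y, 0.0)


def test_median_bandwidth_examples_and_oracle():
    two = np.array([[0.0, 0.0], [1.0, 1.0]])  # distance sqrt 2 -> sigma = 1
    assert median_bandwidth(two) == pytest.approx(1.0)
    dup = np.zeros((3, 2))
    assert median_bandwidth(dup) == 1.0  # degenerate fallback
    rng = np.random.default_rng(2)
    x = rng.standard_normal((20, 4))
    dists = sorted(
        float(np.sum((x[i] - x[j]) ** 2))
        for i in range(20) for j in range(i + 1, 20)
    )
    expected = np.sqrt(np.median(dists) / 2.0)
    assert median_bandwidth(x) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        median_bandwidth(np.zeros((1, 2)))


def test_mmd2_identical_sets_and_singletons():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((6, 3))
    assert mmd2(x, x, 1.0) == pytest.approx(0.0, abs=1e-12)
    a = np.array([[0.0, 0.0]])
    b = np.array([[2.0, 0.0]])
    val = mmd2(a, b, np.sqrt(2.0))  # 2 - 2 kappa at ||a-b||^2 = 2 sigma^2
    assert val == pytest.approx(2 - 2 * np.exp(-1.0), rel=1e-12)


def test_mmd2_four_loop_oracle_and_symmetry():
    rng = np.random.default_rng(7)
    xs, xd = rng.standard_normal((8, 3)), rng.standard_normal((6, 3)) + 0.5
    sigma = 1.1

    def kappa(u, v):
        return np.exp(-np.sum((u - v) ** 2) / (2 * sigma**2))

    t1 = sum(kappa(x, y) for x in xs for y in xs) / 64
    t2 = sum(kappa(x, y) for x in xd for y in xd) / 36
    t3 = sum(kappa(x, y) for x in xs for y in xd) / 48
    expected = t1 + t2 - 2 * t3
    assert mmd2(xs, xd, sigma) == pytest.approx(expected, abs=1e-10)
    assert mmd2(xd, xs, sigma) == pytest.approx(mmd2(xs, xd, sigma), abs=1e-12)
    assert mmd2(xs, xd, sigma) >= -1e-12


def test_mmd2_unbiased_variant():
    rng = np.random.default_rng(8)
    xs, xd = rng.standard_normal((5, 2)), rng.standard_normal((5, 2))
    v = mmd2(xs, xd, 1.0, unbiased=True)
    assert np.isfinite(v)
    with pytest.raises(ValueError):
        mmd2(xs[:1], xd, 1.0, unbiased=True)
    with pytest.raises(ValueError):
        mmd2(np.empty((0, 2)), xd, 1.0)


def test_mmd2_statistical_monotonicity_in_separation():
    medians = []
    for delta in (0.0, 1.0, 2.0, 4.0):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((100, 4))
            b = rng.standard_normal((100, 4))
            b[:, 0] += delta
            vals.append(mmd2(a, b, median_bandwidth(np.vstack([a, b]))))
        medians.append(np.median(vals))
    assert all(x < y for x, y in zip(medians, medians[1:]))


def test_mmd2_grad_matches_finite_differences():
    rng = np.random.default_rng(9)
    xs, xd = rng.standard_normal((4, 3)), rng.standard_normal((3, 3)) + 1.0
    val, gs, gd = mmd2_grad(xs, xd, 1.2)
    assert val == pytest.approx(mmd2(xs, xd, 1.2), abs=1e-12)
    h = 1e-6
    for arr, grad in ((xs, gs), (xd, gd)):
        for idx in np.ndindex(arr.shape):
            old = arr[idx]
            arr[idx] = old + h
            lp = mmd2(xs, xd, 1.2)
            arr[idx] = old - h
            lm = mmd2(xs, xd, 1.2)
            arr[idx] = old
            assert grad[idx] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-10)


def test_alignment_loss_degenerate_sets_skip():
    emb = np.zeros((4, 2))
    part = Partition(similar_m=[], dissimilar_m=[0, 1], similar_h=[], dissimilar_h=[2, 3])
    value, skipped = alignment_loss(emb, part)
    assert (value, skipped) == (0.0, True)
    part2 = Partition(similar_m=[0], dissimilar_m=[1, 2], similar_h=[], dissimilar_h=[3])
    assert alignment_loss(emb, part2)[1] is True  # singleton below min_set_size


def test_alignment_loss_identical_rows_zero():
    emb = np.tile(np.array([[1.0, 2.0]]), (6, 1))
    part = Partition(similar_m=[0, 1, 2], dissimilar_m=[3, 4, 5],
                     similar_h=[], dissimilar_h=[])
    value, skipped = alignment_loss(emb, part, KernelConfig("fixed", 1.0))
    assert not skipped
    assert value == pytest.approx(0.0, abs=1e-12)


def test_alignment_loss_composes_mmd2():
    rng = np.random.default_rng(11)
    emb = rng.standard_normal((10, 4))
    part = Partition(similar_m=[0, 1, 2], dissimilar_m=[3, 4],
                     similar_h=[5, 6], dissimilar_h=[7, 8, 9])
    value, skipped = alignment_loss(emb, part, KernelConfig("fixed", 1.5))
    sim, dis = part.similar_all, part.dissimilar_all
    assert value == pytest.approx(mmd2(emb[sim], emb[dis], 1.5), abs=1e-12)


def test_alignment_loss_grad_finite_differences():
    rng = np.random.default_rng(12)
    emb = rng.standard_normal((6, 3))
    part = Partition(similar_m=[0, 1], dissimilar_m=[2, 3],
                     similar_h=[4], dissimilar_h=[5])
    kc = KernelConfig("fixed", 1.0)
    value, grad, skipped, sigma = alignment_loss_grad(emb, part, kc)
    assert not skipped and sigma == 1.0
    h = 1e-6
    for idx in np.ndindex(emb.shape):
        old = emb[idx]
        emb[idx] = old + h
        lp, _ = alignment_loss(emb, part, kc)
        emb[idx] = old - h
        lm, _ = alignment_loss(emb, part, kc)
        emb[idx] = old
        assert grad[idx] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-10)


def test_kernel_config_validation():
    with pytest.raises(ValueError):
        KernelConfig("fixed", None)
    with pytest.raises(ValueError):
        KernelConfig("bogus")
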