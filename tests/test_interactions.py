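import itertools

import numpy as np
import pytest
from scipy import stats

from hoistab.interactions import (
    TensorOptions,
    generate_ensemble,
    scale,
    scaled_community,
)


def test_shapes_and_seed_determinism():
    ens1 = generate_ensemble(5, seed=42)
    ens2 = generate_ensemble(5, seed=42)
    assert ens1.a_tilde.shape == (5, 5)
    assert ens1.b_tilde.shape == (5, 5, 5)
    assert ens1.c_tilde.shape == (5, 5, 5, 5)
    for t1, t2 in [(ens1.a_tilde, ens2.a_tilde), (ens1.b_tilde, ens2.b_tilde), (ens1.c_tilde, ens2.c_tilde)]:
        assert t1.tobytes() == t2.tobytes()
    ens3 = generate_ensemble(5, seed=43)
    assert not np.array_equal(ens1.a_tilde, ens3.a_tilde)


@pytest.mark.parametrize("distribution", ["gaussian", "uniform", "laplace"])
def test_entries_standardized_for_every_distribution(distribution):
    # N=30 gives ~8e5 four-way entries; the sample variance of a
    # unit-variance i.i.d. draw has relative sd sqrt(2/n) (chi-square), so
    # 5 sigma brackets are tight.  Variance is checked over the nonzero
    # support (structurally masked entries are exactly zero).
    ens = generate_ensemble(30, seed=7, options=TensorOptions(distribution=distribution))
    for t in (ens.a_tilde, ens.b_tilde, ens.c_tilde):
        vals = t[t != 0.0]
        n = vals.size
        assert abs(vals.mean()) < 5.0 / np.sqrt(n)
        assert abs(vals.var() - 1.0) < 5.0 * np.sqrt(2.0 / n)


def test_connectance_controls_nonzero_fraction():
    c = 0.5
    ens = generate_ensemble(8, seed=11, options=TensorOptions(connectance=c, exclude_focal=False))
    for t in (ens.a_tilde, ens.b_tilde, ens.c_tilde):
        k = np.count_nonzero(t)
        n = t.size
        lo, hi = stats.binom.ppf([0.005, 0.995], n, c)
        assert lo <= k <= hi
        # surviving entries keep unit variance
        nz = t[t != 0]
        assert abs(nz.var() - 1.0) < 5.0 * np.sqrt(2.0 / nz.size)


def test_strict_order_mask_by_enumeration():
    n = 4
    ens = generate_ensemble(n, seed=3, options=TensorOptions(strict_order=True))
    for i, j, k in itertools.product(range(n), repeat=3):
        allowed = j > k and len({i, j, k}) == 3
        if not allowed:
            assert ens.b_tilde[i, j, k] == 0.0
    # per focal species: one entry per unordered pair of distinct others
    for i in range(n):
        assert np.count_nonzero(ens.b_tilde[i]) == 3  # C(3, 2)
    for i, j, k, l in itertools.product(range(n), repeat=4):
        allowed = j > k > l and len({i, j, k, l}) == 4
        if not allowed:
            assert ens.c_tilde[i, j, k, l] == 0.0


def test_exclude_diagonal_mask_by_enumeration():
    n = 4
    ens = generate_ensemble(n, seed=3, options=TensorOptions(exclude_diagonal=True))
    for i, j, k in itertools.product(range(n), repeat=3):
        if len({i, j, k}) < 3:
            assert ens.b_tilde[i, j, k] == 0.0
    # pairwise matrix is not masked (self-limitation is the separate -x term)
    assert np.count_nonzero(ens.a_tilde) == n * n


def test_exclude_focal_mask_by_enumeration():
    # baseline convention: high-order terms are modulations by other
    # species; trailing indices never include the focal species, but may
    # repeat among themselves
    n = 4
    ens = generate_ensemble(n, seed=3)
    for i, j, k in itertools.product(range(n), repeat=3):
        if i in (j, k):
            assert ens.b_tilde[i, j, k] == 0.0
        else:
            assert ens.b_tilde[i, j, k] != 0.0  # repeats j == k allowed
    for i in range(n):
        assert np.count_nonzero(ens.c_tilde[i]) == (n - 1) ** 3
    assert np.count_nonzero(ens.a_tilde) == n * n  # pairwise unmasked


def test_structural_flag_implications():
    assert TensorOptions(strict_order=True).exclude_diagonal
    assert TensorOptions(exclude_diagonal=True).exclude_focal


def test_scale_is_sqrt_variance_scaling():
    ens = generate_ensemble(30, seed=5)
    scaled = scale(ens, 0.04, 0.0, 2.5)
    assert np.allclose(scaled.a, 0.2 * ens.a_tilde)
    v = scaled.a.ravel().var()
    assert abs(v - 0.04) < 5 * 0.04 * np.sqrt(2.0 / scaled.a.size)
    assert not scaled.b.any()
    nz = scaled.c[scaled.c != 0.0]
    assert abs(nz.var() - 2.5) < 5 * 2.5 * np.sqrt(2.0 / nz.size)
    # identity scaling
    same = scale(ens, 1.0, 1.0, 1.0)
    assert np.array_equal(same.a, ens.a_tilde)


def test_scaled_community_matches_full_ensemble():
    ens = generate_ensemble(6, seed=99)
    full = scale(ens, 0.1, 0.2, 0.3)
    lean = scaled_community(6, 99, 0.1, 0.2, 0.3)
    for t_full, t_lean in [(full.a, lean.a), (full.b, lean.b), (full.c, lean.c)]:
        assert t_full.tobytes() == t_lean.tobytes()
    # zero-strength orders are skipped entirely, others unchanged
    lean2 = scaled_community(6, 99, 0.1, 0.0, 0.0)
    assert lean2.b is None and lean2.c is None
    assert lean2.a.tobytes() == full.a.tobytes()


@pytest.mark.parametrize(
    "call",
    [
        lambda: generate_ensemble(1, seed=0),
        lambda: TensorOptions(connectance=0.0),
        lambda: TensorOptions(connectance=1.5),
        lambda: TensorOptions(distribution="cauchy"),
        lambda: scale(generate_ensemble(3, seed=0), -0.1, 0.0, 0.0),
        lambda: scaled_community(4, 0, 0.1, -1.0, 0.0),
    ],
)
def test_invalid_arguments_raise(call):
    with pytest.raises(ValueError):
        call()
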