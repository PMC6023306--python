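"""Normalization, the two correlation oracles, block planning, and the
blocked condensed computation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import voxcorr as vc
from voxcorr.engine import BACKENDS

from conftest import condensed_oracle

# ---------------------------------------------------------------------------
# normalization


def test_normalize_rows_hand_example():
    ts = vc.TimeSeriesMatrix([[1.0, 2.0, 3.0]])
    nm = vc.normalize_rows(ts, precision="f64")
    r = 1.0 / np.sqrt(2.0)
    np.testing.assert_allclose(nm.values[0], [-r, 0.0, r], atol=1e-15)
    assert not nm.degenerate_mask[0]


def test_normalize_rows_flags_constant_row():
    ts = vc.TimeSeriesMatrix([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]])
    nm = vc.normalize_rows(ts, precision="f64")
    assert nm.degenerate_mask.tolist() == [True, False]
    np.testing.assert_array_equal(nm.values[0], 0.0)


@pytest.mark.parametrize("precision, tol", [("f64", 1e-12), ("f32", 1e-6)])
def test_normalize_rows_invariants(rng, precision, tol):
    ts = vc.TimeSeriesMatrix(rng.normal(size=(10, 8)) * 100 + 50)
    nm = vc.normalize_rows(ts, precision=precision)
    v = nm.values.astype(np.float64)
    np.testing.assert_allclose(v.mean(axis=1), 0.0, atol=tol)
    np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=tol)


def test_normalized_dot_equals_direct_pcc(rng):
    a = rng.normal(size=(10, 8))
    nm = vc.normalize_rows(vc.TimeSeriesMatrix(a), precision="f64")
    for i in range(10):
        for j in range(i + 1, 10):
            assert abs(nm.values[i] @ nm.values[j] - vc.pcc_direct(a[i], a[j])) < 1e-12


def test_non_finite_input_names_offending_row():
    with pytest.raises(vc.DataError, match=r"\[1\]"):
        vc.TimeSeriesMatrix([[1.0, 2.0], [np.nan, 0.0]])


# ---------------------------------------------------------------------------
# the two scalar oracles


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 0, 0, 1], [0, 1, 1, 0], -1.0),
        ([0, 1], [0, 1], 1.0),
    ],
)
def test_perfect_correlations(x, y, expected):
    assert vc.pcc_direct(x, y) == pytest.approx(expected, abs=1e-15)
    assert vc.pcc_single_pass(x, y) == pytest.approx(expected, abs=1e-9)


def test_constant_series_yields_nan_sentinel():
    assert np.isnan(vc.pcc_direct([2, 2, 2], [1, 2, 3]))
    assert np.isnan(vc.pcc_single_pass([2, 2, 2], [1, 2, 3]))


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        vc.pcc_direct([1, 2, 3], [1, 2])


def test_cross_oracle_agreement(rng):
    """Centered and raw-moment formulas agree to 1e-10 on well-conditioned data."""
    worst = 0.0
    for _ in range(100):
        x, y = rng.normal(size=(2, 32))
        worst = max(worst, abs(vc.pcc_direct(x, y) - vc.pcc_single_pass(x, y)))
    assert worst <= 1e-10


def test_oracles_match_scipy(rng):
    a = rng.normal(size=(12, 30))
    ref = 1.0 - pdist(a, metric="correlation")
    np.testing.assert_allclose(condensed_oracle(a), ref, atol=1e-12)


# ---------------------------------------------------------------------------
# block planning


def test_plan_worked_trace_n5_x20():
    """Two rounds: B=⌊20/10⌋=2 over N′=5 (7 outputs), then B=⌊20/6⌋=3
    clamped to N′=3 (3 outputs); the 10 outputs tile triangle_size(5)."""
    plan = vc.plan_blocks(5, 3, 20)
    trace = [(r.start, r.block_size, r.remaining, r.out_length) for r in plan.rounds]
    assert trace == [(0, 2, 5, 7), (2, 3, 3, 3)]
    assert not plan.single_round
    assert plan.total_out_length == vc.triangle_size(5)


def test_plan_single_round_when_budget_ample():
    plan = vc.plan_blocks(5, 3, 1000)  # candidate B = 100 > 5
    assert plan.single_round
    assert [(r.start, r.block_size, r.remaining) for r in plan.rounds] == [(0, 5, 5)]


def test_plan_infeasible_budget_reports_minimum():
    with pytest.raises(vc.BudgetError, match="200"):
        vc.plan_blocks(100, 10, 199)


@pytest.mark.parametrize("budget", [200, 317, 1000, 9999, 10**6])
def test_plan_tiles_every_pair_exactly_once(budget):
    n = 100
    plan = vc.plan_blocks(n, 10, budget)
    seen = np.zeros(vc.triangle_size(n), dtype=int)
    offset = 0
    covered_start = 0
    for r in plan.rounds:
        assert r.start == covered_start and r.out_offset == offset
        assert 1 <= r.block_size <= r.remaining
        assert r.remaining == n - r.start
        assert r.out_length == r.remaining * r.block_size - r.block_size * (r.block_size + 1) // 2
        for a in range(r.block_size):
            gi = r.start + a
            ks = vc.pair_to_linear(np.full(n - gi - 1, gi),
                                   np.arange(gi + 1, n), n)
            seen[ks] += 1
        offset += r.out_length
        covered_start += r.block_size
    assert covered_start == n
    assert np.all(seen == 1)


def test_plan_follows_block_size_recurrence():
    n, x = 200, 4000
    plan = vc.plan_blocks(n, 100, x)
    remaining = n
    for r in plan.rounds:
        assert r.remaining == remaining
        b = x // (2 * remaining)
        assert r.block_size == min(b, remaining)
        remaining -= r.block_size
    assert remaining == 0


# ---------------------------------------------------------------------------
# per-round product and extraction


def test_block_products_full_round(anticorrelated_trio):
    nm = vc.normalize_rows(anticorrelated_trio, precision="f64")
    rnd = vc.BlockRound(start=0, block_size=3, remaining=3, out_offset=0, out_length=3)
    s = vc.block_products(nm, rnd)
    np.testing.assert_allclose(s, [[1, -1, 1], [-1, 1, -1], [1, -1, 1]], atol=1e-15)
    np.testing.assert_allclose(vc.extract_upper_block(s, rnd), [-1, 1, -1], atol=1e-15)


def test_block_products_diagonal_is_unity(rng):
    nm = vc.normalize_rows(vc.TimeSeriesMatrix(rng.normal(size=(20, 16))),
                           precision="f64")
    rnd = vc.BlockRound(start=5, block_size=4, remaining=15, out_offset=0,
                        out_length=15 * 4 - 10)
    s = vc.block_products(nm, rnd)
    np.testing.assert_allclose(np.diag(s)[:4], 1.0, atol=1e-12)


def test_block_products_match_direct_oracle(rng):
    a = rng.normal(size=(20, 16))
    nm = vc.normalize_rows(vc.TimeSeriesMatrix(a), precision="f32")
    rnd = vc.BlockRound(start=7, block_size=5, remaining=13, out_offset=0,
                        out_length=13 * 5 - 15)
    s = vc.block_products(nm, rnd)
    for la in range(5):
        for lb in range(13):
            assert abs(s[la, lb] - vc.pcc_direct(a[7 + la], a[7 + lb])) < 1e-6


def test_extract_upper_block_order():
    # B=2, N'=5: local pairs (0,1)..(0,4),(1,2),(1,3),(1,4) in that order
    s = np.arange(10.0).reshape(2, 5)
    rnd = vc.BlockRound(start=0, block_size=2, remaining=5, out_offset=0, out_length=7)
    np.testing.assert_array_equal(vc.extract_upper_block(s, rnd),
                                  [1, 2, 3, 4, 7, 8, 9])


def test_extract_upper_block_shape_mismatch():
    rnd = vc.BlockRound(start=0, block_size=2, remaining=5, out_offset=0, out_length=7)
    with pytest.raises(ValueError):
        vc.extract_upper_block(np.zeros((3, 5)), rnd)


def test_backend_contract_rejects_bad_shape():
    nm = vc.normalize_rows(vc.TimeSeriesMatrix(np.eye(4)), precision="f64")
    rnd = vc.BlockRound(start=0, block_size=2, remaining=4, out_offset=0, out_length=5)
    with pytest.raises(vc.BackendError, match="shape"):
        vc.block_products(nm, rnd, backend=lambda b, r: np.zeros((1, 1)))


# ---------------------------------------------------------------------------
# end-to-end condensed computation


def test_compute_condensed_trivial(anticorrelated_trio):
    for budget in (7, 50, 10**6):
        c, _ = vc.compute_condensed(anticorrelated_trio, budget, precision="f64")
        np.testing.assert_allclose(c.values, [-1, 1, -1], atol=1e-15)


def test_compute_condensed_matches_bruteforce(rng):
    a = rng.normal(size=(50, 20))
    c, _ = vc.compute_condensed(vc.TimeSeriesMatrix(a), 10**6, precision="f64")
    assert np.abs(c.values - condensed_oracle(a)).max() <= 1e-12


def test_budget_invariance(rng):
    a = rng.normal(size=(50, 20))
    ts = vc.TimeSeriesMatrix(a)
    results = [
        vc.compute_condensed(ts, x, precision="f64")[0].values
        for x in (2 * 50 + 1, 500, 10**6)
    ]
    for other in results[1:]:
        assert np.abs(results[0] - other).max() <= 1e-12


@pytest.mark.parametrize("backend", sorted(BACKENDS))
def test_backends_satisfy_same_contract(rng, backend):
    a = rng.normal(size=(30, 12))
    c, _ = vc.compute_condensed(vc.TimeSeriesMatrix(a), 10**5, precision="f64",
                                backend=backend)
    assert np.abs(c.values - condensed_oracle(a)).max() <= 1e-12


def test_affine_invariance(rng):
    """Correlations are invariant under positive affine rescaling of any
    voxel and flip sign under negative scaling."""
    a = rng.normal(size=(12, 25))
    base, _ = vc.compute_condensed(vc.TimeSeriesMatrix(a), 10**5, precision="f64")
    b = a.copy()
    b[3] = 2.5 * b[3] - 7.0
    pos, _ = vc.compute_condensed(vc.TimeSeriesMatrix(b), 10**5, precision="f64")
    assert np.abs(pos.values - base.values).max() <= 1e-12
    b[3] = -b[3]
    neg, _ = vc.compute_condensed(vc.TimeSeriesMatrix(b), 10**5, precision="f64")
    n = 12
    flipped = base.values.copy()
    others = np.concatenate([np.arange(3), np.arange(4, n)])
    ks = vc.pair_to_linear(np.minimum(others, 3), np.maximum(others, 3), n)
    flipped[ks] = -flipped[ks]
    assert np.abs(neg.values - flipped).max() <= 1e-12


def test_output_range_bound(rng):
    m = 64
    a = rng.uniform(-6, 6, size=(40, m))
    c, _ = vc.compute_condensed(vc.TimeSeriesMatrix(a), 10**4, precision="f32")
    eps = np.finfo(np.float32).eps
    assert np.abs(c.values).max() <= 1.0 + 4 * eps * m


def test_identical_series_correlate_to_one(rng):
    m = 32
    a = rng.normal(size=(5, m))
    a[4] = a[0]
    c, _ = vc.compute_condensed(vc.TimeSeriesMatrix(a), 10**4, precision="f64")
    k = vc.pair_to_linear(0, 4, 5)
    assert abs(c.values[k] - 1.0) <= 8 * np.finfo(np.float64).eps * m


# ---------------------------------------------------------------------------
# degenerate-voxel policies


@pytest.fixture
def with_flat_voxel(rng):
    a = rng.normal(size=(6, 10))
    a[2] = 3.14
    return vc.TimeSeriesMatrix(a)


def test_degenerate_policy_nan(with_flat_voxel):
    with pytest.warns(UserWarning, match="degenerate"):
        c, _ = vc.compute_condensed(with_flat_voxel, 10**4, precision="f64")
    n = 6
    i, j = vc.linear_to_pair(np.arange(vc.triangle_size(n)), n)
    touches = (i == 2) | (j == 2)
    assert np.all(np.isnan(c.values[touches]))
    assert not np.any(np.isnan(c.values[~touches]))


def test_degenerate_policy_zero(with_flat_voxel):
    with pytest.warns(UserWarning):
        c, _ = vc.compute_condensed(with_flat_voxel, 10**4, precision="f64",
                                    degenerate_policy="zero")
    k = vc.pair_to_linear(1, 2, 6)
    assert c.values[k] == 0.0


def test_degenerate_policy_error_names_voxel(with_flat_voxel):
    with pytest.raises(vc.DegenerateVoxelError, match="voxel 2"):
        vc.compute_condensed(with_flat_voxel, 10**4, degenerate_policy="error")
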