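"""Blocked all-pairs Pearson correlation under a working-memory budget.

The method
----------
Center each voxel's time series and scale it to unit L2 norm,

    u_i = (v_i − v̄_i) / ‖v_i − v̄_i‖₂ ,

after which the Pearson correlation of voxels i and j is the plain dot
product u_i·u_j, and the whole correlation matrix is U Uᵀ — one dense
matrix product. The matrix has N(N−1)/2 distinct entries (strict upper
triangle); for voxel-level fMRI, N is 10^4–10^5 and the full N×N product
does not fit in a working buffer, so the product is computed in *rounds*:
each round multiplies a block of B consecutive voxel rows against all
not-yet-finished voxels (an N′-column slab), extracts the strictly-upper
local triangle in row-major order, and appends it to the condensed output
array. The block size comes from the budget X (in scalar elements of the
working precision):

    B = ⌊ X / 2N′ ⌋ ,

because a round needs at most N′B elements for the product plus
N′B − B(B+1)/2 for the extracted slice, bounded above by 2N′B. After the
round, N′ shrinks by B and B is recomputed, clamped to N′ on the last
round. If the very first candidate B exceeds N, everything fits in a
single round and the plan degenerates to the full product.

The condensed output is identical — up to floating-point tolerance, since
summation order inside a dot product is backend-defined — for every
feasible budget; that invariance is the contract the test suite enforces.

Degenerate voxels (constant series) have no defined correlation; their
rows normalize to zero and their pairs are patched per policy
(``nan`` default, ``zero``, or ``error``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BackendError, BudgetError, DataError, DegenerateVoxelError
from .indexing import pair_to_linear, triangle_size

__all__ = [
    "TimeSeriesMatrix",
    "NormalizedMatrix",
    "BlockRound",
    "BlockPlan",
    "CondensedCorrelationArray",
    "normalize_rows",
    "pcc_direct",
    "pcc_single_pass",
    "plan_blocks",
    "block_products",
    "extract_upper_block",
    "compute_condensed",
    "get_backend",
    "register_backend",
    "BACKENDS",
]

_DTYPES = {"f32": np.float32, "f64": np.float64}
# default degenerate thresholds: centered norm <= eps * sqrt(M)
_DEGEN_EPS = {"f32": 1e-6, "f64": 1e-12}


@dataclass
class TimeSeriesMatrix:
    """An N×M matrix of raw voxel time series (rows = voxels, cols = timepoints).

    ``voxel_order_tag`` records where the row order came from (file layout,
    volume flattening convention, synthetic generator id) so a condensed
    array can always be traced back to a voxel ordering.
    """

    values: np.ndarray
    voxel_order_tag: str = "unspecified"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataError(
                f"time-series matrix must be 2-D (voxels x timepoints), "
                f"got shape {self.values.shape}"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            rows = np.unique(np.nonzero(bad)[0])
            raise DataError(
                f"non-finite values in time series of voxel(s) {rows[:10].tolist()}"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedMatrix:
    """Row-centered, row-unit-norm matrix; correlations are now dot products.

    ``degenerate_mask`` flags constant rows (centered norm below threshold),
    which are zeroed rather than divided by ~0.
    """

    values: np.ndarray
    degenerate_mask: np.ndarray
    precision: str = "f64"

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def degenerate_voxels(self) -> np.ndarray:
        return np.nonzero(self.degenerate_mask)[0]


@dataclass
class BlockRound:
    """One round of the blocked product.

    start      first global voxel index of the block
    block_size B, number of voxel rows multiplied this round
    remaining  N′, number of not-yet-finished voxels (columns of the slab)
    out_offset 0-based position of this round's slice in the condensed array
    out_length N′B − B(B+1)/2 extracted coefficients
    """

    start: int
    block_size: int
    remaining: int
    out_offset: int
    out_length: int


@dataclass
class BlockPlan:
    """Ordered rounds realizing the blocked computation under a budget."""

    n_voxels: int
    budget_elements: int
    rounds: list[BlockRound] = field(default_factory=list)
    single_round: bool = False

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def total_out_length(self) -> int:
        return sum(r.out_length for r in self.rounds)


@dataclass
class CondensedCorrelationArray:
    """Length-N(N−1)/2 array of correlations, strict upper triangle, row-major."""

    values: np.ndarray
    n_voxels: int
    order_tag: str = "upper-row-major"
    precision: str = "f64"
    degenerate_voxels: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    degenerate_policy: str = "nan"

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# normalization and the two scalar-correlation oracles


def normalize_rows(
    ts: TimeSeriesMatrix,
    precision: str = "f64",
    degenerate_eps: float | None = None,
) -> NormalizedMatrix:
    """Center each row and scale to unit L2 norm; flag degenerate rows.

    The centering/scaling arithmetic runs in float64 regardless of the
    working precision — this is the cheap O(NM) stage, and doing it in
    double keeps the working-precision error budget entirely inside the
    O(N²M) product stage. The result is cast to ``precision``.

    Rows whose centered norm is ≤ degenerate_eps·√M (default eps 1e−12 for
    f64, 1e−6 for f32) are constant up to noise at working precision; they
    are zeroed and flagged instead of being divided by ~0.
    """
    if precision not in _DTYPES:
        raise ValueError(f"precision must be one of {sorted(_DTYPES)}, got {precision!r}")
    if ts.n_timepoints < 2:
        raise DataError(f"need at least 2 timepoints, got {ts.n_timepoints}")
    if degenerate_eps is None:
        degenerate_eps = _DEGEN_EPS[precision]
    m = ts.n_timepoints
    centered = ts.values - ts.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms <= degenerate_eps * np.sqrt(m)
    safe = np.where(degenerate, 1.0, norms)
    out = centered / safe[:, None]
    out[degenerate] = 0.0
    return NormalizedMatrix(
        values=out.astype(_DTYPES[precision], copy=False),
        degenerate_mask=degenerate,
        precision=precision,
    )


def pcc_direct(x, y) -> float:
    """Pearson correlation in its definitional centered form.

        r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² · Σ(yᵢ−ȳ)²)

    Returns NaN when either series is constant (zero centered norm).
    This is the reference oracle the blocked engine is tested against.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def pcc_single_pass(x, y) -> float:
    """Pearson correlation from raw moments (single-pass form).

        r = (T·Σxy − Σx·Σy) / √(T·Σx² − (Σx)²) · √(T·Σy² − (Σy)²)

    Algebraically identical to :func:`pcc_direct` but numerically
    independent (no centering), so it serves as a second oracle; on
    well-conditioned data the two agree to ~1e−10 in double precision.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_pair(x, y)
    t = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    dx = t * sxx - sx * sx
    dy = t * syy - sy * sy
    if dx <= 0.0 or dy <= 0.0:
        return float("nan")
    return float((t * sxy - sx * sy) / (np.sqrt(dx) * np.sqrt(dy)))


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError(
            f"expected two equal-length 1-D vectors, got shapes {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValueError("correlation needs at least 2 timepoints")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in correlation input")


# ---------------------------------------------------------------------------
# block planning


def plan_blocks(n: int, m: int, budget_elements: int) -> BlockPlan:
    """Build the round schedule for ``n`` voxels under a budget of
    ``budget_elements`` working-precision scalars.

    The budget covers the per-round product buffer plus the per-round
    condensed slice (≤ 2N′B elements); the normalized N×M matrix is held
    separately and is not charged against it. The first candidate block
    size is B = ⌊X/2n⌋; if that exceeds n the whole triangle fits in one
    round. Otherwise rounds are emitted with B recomputed from the
    remaining count N′ after each, clamped to N′ at the end. The resulting
    rounds tile the strict upper triangle exactly once.
    """
    n = int(n)
    m = int(m)
    budget_elements = int(budget_elements)
    if n < 2:
        raise ValueError(f"need at least 2 voxels to correlate, got {n}")
    if budget_elements < 2 * n:
        raise BudgetError(
            f"budget of {budget_elements} elements cannot fit any round for "
            f"n={n}: minimum feasible budget is 2n = {2 * n} elements "
            f"(one voxel row against all voxels plus its output slice)"
        )
    plan = BlockPlan(n_voxels=n, budget_elements=budget_elements)
    b = budget_elements // (2 * n)
    if b > n:
        plan.single_round = True
        plan.rounds.append(
            BlockRound(start=0, block_size=n, remaining=n, out_offset=0,
                       out_length=triangle_size(n))
        )
        return plan
    start, remaining, offset = 0, n, 0
    while start < n:
        if b > remaining:
            b = remaining
        out_len = remaining * b - b * (b + 1) // 2
        plan.rounds.append(
            BlockRound(start=start, block_size=b, remaining=remaining,
                       out_offset=offset, out_length=out_len)
        )
        start += b
        remaining -= b
        offset += out_len
        if remaining > 0:
            b = budget_elements // (2 * remaining)
    assert plan.total_out_length == triangle_size(n)
    return plan


# ---------------------------------------------------------------------------
# product backends

def _matmul_backend(block: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Dense BLAS gemm: block (B×M) @ rest.T (M×N′)."""
    return block @ rest.T


def _einsum_backend(block: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """einsum route; same contract, different reduction machinery."""
    return np.einsum("am,bm->ab", block, rest)


BACKENDS: dict = {"matmul": _matmul_backend, "einsum": _einsum_backend}


def get_backend(backend):
    """Resolve a backend name or accept a callable satisfying the contract:
    (B×M block rows, N′×M remaining rows) → B×N′ product, pure function."""
    if callable(backend):
        return backend
    try:
        return BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown backend {backend!r}; registered: {sorted(BACKENDS)}"
        ) from None


def register_backend(name: str, fn) -> None:
    """Register an additional product backend (e.g. an accelerated one).

    Accelerated backends must satisfy the same elementwise tolerance
    contract as the reference; the test suite's budget-invariance and
    oracle checks apply to any registered backend unchanged.
    """
    BACKENDS[name] = fn


# ---------------------------------------------------------------------------
# per-round product and extraction


def block_products(nm: NormalizedMatrix, rnd: BlockRound, backend="matmul") -> np.ndarray:
    """Multiply one round's block rows against all not-yet-finished rows.

    Entry (a, b) is dot(u[start+a], u[start+b]): the B×N′ sub-block of the
    correlation matrix whose rows are the block voxels and whose columns
    are global voxels start..n−1. The block is the slab's first B columns,
    so its diagonal holds the block voxels' self-correlations (≈1).
    """
    start, b, rem = rnd.start, rnd.block_size, rnd.remaining
    if start + rem != nm.n_voxels or not (1 <= b <= rem):
        raise ValueError(
            f"round (start={start}, B={b}, N'={rem}) inconsistent with "
            f"matrix of {nm.n_voxels} voxels"
        )
    fn = get_backend(backend)
    block = nm.values[start : start + b]
    rest = nm.values[start:]
    try:
        s = fn(block, rest)
    except Exception as exc:  # noqa: BLE001 - backend is third-party code
        raise BackendError(
            f"backend {backend!r} failed on round start={start} B={b} N'={rem}: {exc}"
        ) from exc
    s = np.asarray(s)
    if s.shape != (b, rem):
        raise BackendError(
            f"backend {backend!r} returned shape {s.shape}, expected {(b, rem)} "
            f"for round start={start}"
        )
    return s


def extract_upper_block(s: np.ndarray, rnd: BlockRound) -> np.ndarray:
    """Extract the strictly-upper local triangle of a round's B×N′ product,
    ordered row-major: local pairs (a, b) with a < b at position
    a·N′ − a(a+1)/2 + b − a − 1. Length N′B − B(B+1)/2.

    When the round covers the full matrix (B = N′ = N) this is exactly the
    full condensed array.
    """
    b, rem = rnd.block_size, rnd.remaining
    if s.shape != (b, rem):
        raise ValueError(f"product shape {s.shape} does not match round ({b}, {rem})")
    out = np.empty(rnd.out_length, dtype=s.dtype)
    pos = 0
    for a in range(b):
        seg = rem - a - 1  # columns a+1 .. N'-1
        out[pos : pos + seg] = s[a, a + 1 :]
        pos += seg
    assert pos == rnd.out_length
    return out


# ---------------------------------------------------------------------------
# driver


def compute_condensed(
    ts: TimeSeriesMatrix,
    budget_elements: int,
    precision: str = "f32",
    degenerate_policy: str = "nan",
    backend="matmul",
    degenerate_eps: float | None = None,
    plan: BlockPlan | None = None,
) -> tuple[CondensedCorrelationArray, BlockPlan]:
    """All-pairs Pearson correlations of ``ts`` as a condensed array.

    Normalizes rows, builds the block plan for ``budget_elements`` working
    scalars, then runs each round (product + upper-triangle extraction),
    writing the slice at its planned offset. The result is budget-invariant
    up to working-precision tolerance.

    degenerate_policy : how pairs touching a constant voxel are reported —
        ``nan`` (sentinel, default), ``zero``, or ``error`` (abort naming
        the first flagged voxel).

    Returns the condensed array and the executed plan (the round trace).
    """
    if degenerate_policy not in ("nan", "zero", "error"):
        raise ValueError(
            f"degenerate_policy must be nan|zero|error, got {degenerate_policy!r}"
        )
    nm = normalize_rows(ts, precision=precision, degenerate_eps=degenerate_eps)
    degenerate = nm.degenerate_voxels
    if degenerate_policy == "error" and degenerate.size:
        raise DegenerateVoxelError(
            f"voxel {int(degenerate[0])} has a constant time series "
            f"({degenerate.size} degenerate voxel(s) total)"
        )
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} degenerate voxel(s) with constant time series; "
            f"their correlations are set per policy {degenerate_policy!r}",
            stacklevel=2,
        )
    n = ts.n_voxels
    if plan is None:
        plan = plan_blocks(n, ts.n_timepoints, budget_elements)
    values = np.empty(triangle_size(n), dtype=_DTYPES[precision])
    for rnd in plan.rounds:
        s = block_products(nm, rnd, backend=backend)
        values[rnd.out_offset : rnd.out_offset + rnd.out_length] = (
            extract_upper_block(s, rnd)
        )
    if degenerate.size and degenerate_policy == "nan":
        _patch_degenerate(values, degenerate, n, np.nan)
    # policy "zero": rows were zeroed, products already 0 — nothing to patch
    return (
        CondensedCorrelationArray(
            values=values,
            n_voxels=n,
            precision=precision,
            degenerate_voxels=degenerate,
            degenerate_policy=degenerate_policy,
        ),
        plan,
    )


def _patch_degenerate(values, degenerate, n, fill) -> None:
    """Overwrite every condensed position touching a degenerate voxel."""
    others = np.arange(n, dtype=np.int64)
    for v in degenerate:
        o = others[others != v]
        k = pair_to_linear(np.minimum(o, v), np.maximum(o, v), n)
        values[k] = fill
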