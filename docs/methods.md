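# Methods

## Model and reduction

The quantity computed is the Pearson correlation of every unordered pair
of rows of an N×M voxel-by-timepoint matrix. The engine never evaluates
the definitional formula pairwise; it uses the normalization reduction:
each row v is centered and scaled to unit L2 norm, u = (v − v̄)/‖v − v̄‖₂,
after which r(vᵢ, vⱼ) = uᵢ·uⱼ and the full correlation matrix is the
Gram matrix U Uᵀ. The definitional centered formula (`pcc_direct`) and
the raw-moment single-pass formula (`pcc_single_pass`) are kept in the
package purely as independent oracles; the test suite and `verify`
subcommand check the Gram-matrix path against both, and against
`scipy.spatial.distance.pdist(metric="correlation")` as a third,
third-party route.

## Condensed layout and index maps

Only the strict upper triangle is stored, row-major:

    k(i, j) = i·N − i(i+1)/2 + j − i − 1,    0 ≤ i < j < N,

a 0-based bijection onto 0 … N(N−1)/2 − 1. The first N−1 positions are
voxel 0's correlations, the next N−2 voxel 1's, and so on. The inverse
map recovers the row index from the integer square root of the
discriminant of the triangular-number equation, counted from the array's
end, followed by a bounded ±1 correction against exact row offsets. A
closed form based on floating-point `sqrt` mis-rounds for large k, so the
implementation is integer-exact by construction and the *bijection
property* — verified exhaustively for all N ≤ 500 and sampled up to
N = 10⁶ — is the contract, not any particular printed formula. All index
arithmetic is ≥64-bit (N = 100 000 already yields ~5 × 10⁹ positions).

## Block planning and the memory budget

The budget X counts scalar elements of the working precision available
for one round's product buffer plus its extracted output slice. A round
that multiplies B block rows against N′ remaining rows needs
N′B + (N′B − B(B+1)/2) ≤ 2N′B elements, giving the block-size rule

    B = ⌊ X / 2N′ ⌋ .

The normalized N×M matrix itself is held for the whole run and is *not*
charged against X; callers sizing X from physical memory should subtract
N·M·(scalar width) first. Planning is a simple recurrence: start with
N′ = N; if the first candidate B exceeds N the whole triangle is one
round; otherwise emit (start, B, N′), advance start by B, shrink N′ by B,
recompute B, clamping B = N′ on the final round. Floor division is used
throughout (it guarantees the space bound; a ceiling could exceed it).
The plan provably tiles the strict upper triangle exactly once, and the
executed trace is logged and persisted in the store sidecar so the
out-of-core schedule is externally auditable.

Feasibility requires X ≥ 2N (one row against all rows). Below that the
planner raises a budget error naming the minimum.

## Precision and tolerances

Working precision is `f32` (default — the blocked product is
traditionally a single-precision gemm) or `f64`. Normalization always
runs in float64 and the normalized matrix is then cast, so the working
precision governs only the O(N²M) product/accumulation stage; this is the
cheap way to keep the f32 path's end-to-end error at the level of a
single f32 dot product (~√M·ε ≈ 10⁻⁶ at M = 64) rather than compounding
normalization error.

Outputs are *not* clamped to [−1, 1]; floating-point excursions are
bounded by 4ε·M and asserted in tests, and clamping would hide backend
defects. Summation order inside a dot product is backend-defined, so
budget invariance is specified as tolerance-bounded (≤10⁻¹² in f64,
≤10⁻⁶ in f32), never bitwise; observed cross-budget differences are
~10⁻¹⁶ in f64.

Degenerate voxels — rows whose centered norm is ≤ eps·√M with eps 10⁻¹²
(f64) or 10⁻⁶ (f32) — have undefined correlation. They are zeroed at
normalization and their pairs patched per policy: `nan` (default, with a
warning giving the count), `zero`, or `error` (abort naming the first
offending voxel). The threshold is absolute in the centered norm, which
is the natural scale here because the normalization itself divides by it;
data with pathological dynamic range should be rescaled upstream.

## Backend contract

The per-round product is a pure function (B×M block rows, N′×M remaining
rows) → B×N′ matrix. Two implementations ship: `matmul` (NumPy `@`,
i.e. BLAS gemm — the default) and `einsum` (a differently-ordered
reduction, used as an in-package seam check). `register_backend` accepts
accelerated implementations; any backend must pass the same oracle and
budget-invariance tolerances, and backend failures are wrapped with the
identity of the round being executed.

## Synthetic data

`generate_uniform` draws every intensity i.i.d. uniform on [−6, 6] — the
standard scalability benchmark protocol for this computation (typically
M = 100, N up to 10⁵); its expected pairwise correlation is 0, so it
exercises arithmetic and scheduling, not recovery.
`generate_planted` builds x_v = √ρ·g_c + √(1−ρ)·e_v with shared
community factors g_c and private noise e_v, all standard normal:
population correlation ρ within a community, 0 across. Both use NumPy's
PCG64 with an explicit seed; the generator id and seed are recorded in
the matrix's provenance tag, and reproducibility is claimed
per-generator-algorithm, not across libraries.

What the generators do *not* emulate: BOLD hemodynamics, temporal
autocorrelation, spatial smoothness, scanner drift or motion artifacts.
Passing tests therefore certify the engine's numerics, ordering and
scheduling on exchangeable data; they say nothing about preprocessing
choices on real acquisitions, which are out of scope (inputs are assumed
already masked and cleaned).

A sampling caveat that shaped one test: in a planted realization, every
between-community pair correlation shares the same two community
factors, whose sample correlation has sd ≈ ρ/√M (~0.027 at ρ = 0.6,
M = 500). The mean between-community correlation of *one* realization
therefore scatters at that scale no matter how many pairs are averaged,
and a ±0.05 band is only ~1.9σ for a single seed. The recovery test
consequently applies the ±0.05 band to means across 5 seeds (~4σ) while
asserting within > between separation for every individual seed.

## Problem sizes

Tests and the acceptance script run at N ≤ 1000, M ≤ 500 — sizes where
the brute-force all-pairs oracle is itself cheap and exact, which is what
makes elementwise comparison meaningful. The engine's arithmetic is
size-independent (the index maps are exercised to N = 10⁶); scaling to
N ~ 10⁵ changes only wall-clock time and store size (≥64-bit indexing and
the out-of-core schedule already account for it).

## I/O conventions

Delimited text is whitespace- or comma-separated, one voxel per line,
optional single header line. Raw binary is a bare little-endian array
with a JSON sidecar (shape, dtype) — directly memory-mappable. 4-D NIfTI
volumes are flattened with the first spatial axis varying fastest; an
optional 3-D mask on the same grid selects voxels (nonzero = keep). The
flattening convention is recorded in the matrix and store provenance tags
since the condensed array is meaningless without the row order. The
correlation store mirrors the raw-binary convention (headerless data
file + sidecar) and its sidecar carries the degenerate-voxel list, the
executed round trace, and a SHA-256 checksum of the input matrix, so a
store can be audited and re-verified against its source. Pair lookup is
one `seek` + one scalar read at position k(min, max); the diagonal is not
stored (it is 1 by definition).

## Known limitations

- No windowed/dynamic connectivity, covariance or eigen-analysis, or
  correlation thresholding — the deliverable is the full condensed array.
- No preprocessing (detrending, filtering, motion correction).
- The degenerate threshold is absolute in the centered norm (see above).
- f32 stores verified against f64 oracles are tolerance-checked at 10⁻⁵
  by default; single corrupted low-order mantissa bits are below that
  noise floor by construction and only exponent-scale corruption is
  detectable from values alone (the sidecar checksum covers the input,
  not the store payload).
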