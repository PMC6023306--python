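# voxcorr

Memory-budgeted computation of **all pairwise Pearson correlations** of
voxel time series, written out as a single ordered condensed array.

## The problem

Voxel-level functional connectivity analysis of fMRI needs the Pearson
correlation of every pair of voxel time series. With N voxels and M
timepoints (N ~ 10⁴–10⁵, M ~ 100), the correlation matrix has
N(N−1)/2 distinct entries — at N = 100 000 that is ~5 × 10⁹
coefficients, far larger than any reasonable working buffer. `voxcorr`
computes exactly that set, out-of-core, on whatever memory you give it,
and stores it in a layout with O(1) random pair lookup. It is aimed at
neuroimaging and network-inference pipelines that need full voxel-level
(not region-averaged) connectivity.

## The method

For series x, y of length M the Pearson correlation is

    r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √( Σ(xᵢ−x̄)² · Σ(yᵢ−ȳ)² ).

Center each voxel's series and scale to unit L2 norm,
u = (v − v̄)/‖v − v̄‖₂; then r(vᵢ, vⱼ) = uᵢ·uⱼ and the whole matrix is
U Uᵀ — a dense matrix product. Only the strict upper triangle is kept,
flattened row-major so pair (i, j), i < j, lands at

    k = i·N − i(i+1)/2 + j − i − 1 ,

with an exact integer inverse map. Under a working budget of X scalars
the product is executed in rounds: a block of B = ⌊X/2N′⌋ consecutive
voxel rows is multiplied against the N′ not-yet-finished rows, the local
upper triangle is appended to the output, and N′ shrinks by B until the
triangle is tiled — each pair computed exactly once, and the result
identical (to floating-point tolerance) under any feasible budget.

Degenerate voxels (constant series, correlation undefined) are flagged
and reported as NaN by default (`zero` and `error` policies available).

## Worked example

```python
import voxcorr as vc

ts = vc.TimeSeriesMatrix([[1, 2, 3], [3, 2, 1], [1, 2, 3]])
condensed, plan = vc.compute_condensed(ts, budget_elements=1000, precision="f64")
print(condensed.values)          # [-1.  1. -1.]
```

The three values are r(0,1), r(0,2), r(1,2) in condensed order: row 1
runs backwards relative to row 0 (−1), row 2 repeats row 0 (+1).
Blocking at scale (`examples/02_out_of_core_blocking.py`) prints:

```
budget  100000 elements ->  1 round(s): B=200/N'=200
budget   20000 elements ->  3 round(s): B=50/N'=200, B=66/N'=150, B=84/N'=84
budget    4000 elements -> 12 round(s): B=10/N'=200, B=10/N'=190, ...
max |difference| across the three budgets: 1.11e-16
```

— the round schedule changes with the budget, the 19 900 correlations do
not. See `examples/` for the store/query and planted-community scripts.

## Command line

```bash
voxcorr simulate -o ts.txt -n 500 -m 100 --seed 7
voxcorr compute ts.txt -o ts.pcc --budget 512M --precision f32 -v
voxcorr query ts.pcc 12 311          # one correlation, one positioned read
voxcorr verify ts.txt ts.pcc         # spot-check store against both oracles
```

`compute` also reads raw little-endian binaries (with a JSON sidecar) and
4-D NIfTI volumes with an optional 3-D mask; `-v` logs the executed round
trace. The store is a bare memory-mappable array plus a JSON sidecar
recording voxel count, precision, ordering, degenerate voxels, the round
trace and an input checksum.

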