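"""The out-of-core round schedule and its budget invariance.

A 200-voxel uniform synthetic dataset is correlated under three memory
budgets: one large enough for a single full-matrix round, and two that
force blocked multi-round execution. The printed round traces show the
block-size recurrence B = floor(X / 2N'); the max elementwise difference
between the three condensed arrays shows the schedule does not change the
numbers.
"""

import numpy as np

import voxcorr as vc
from voxcorr.synth import SynthSpec

ts = vc.generate_uniform(SynthSpec(n_voxels=200, n_timepoints=100, seed=42))
results = []
for budget in (100_000, 20_000, 4_000):
    condensed, plan = vc.compute_condensed(ts, budget, precision="f64")
    results.append(condensed.values)
    trace = ", ".join(f"B={r.block_size}/N'={r.remaining}" for r in plan.rounds[:5])
    more = " ..." if plan.n_rounds > 5 else ""
    print(f"budget {budget:>7} elements -> {plan.n_rounds:>2} round(s): {trace}{more}")

diff = max(np.abs(a - b).max() for a in results for b in results)
print(f"max |difference| across the three budgets: {diff:.2e}")
# The schedule changes; the N(N-1)/2 correlations do not (up to ~1e-16).
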