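"""Deterministic synthetic voxel time series.

Two generators, both seeded with NumPy's PCG64 (the generator algorithm is
recorded in the matrix's order tag, since seeded reproducibility is only
meaningful per-algorithm):

* ``uniform`` — every intensity i.i.d. uniform on [−6, 6], the standard
  scalability benchmark for all-pairs correlation engines (N voxels, M
  timepoints, typically M = 100). Expected pairwise correlations are 0.
* ``planted`` — a block-community correlation structure for recovery
  tests: voxel v in community c gets

      x_v = √ρ · g_c + √(1−ρ) · e_v

  with g_c (shared per community) and e_v (private) i.i.d. standard
  normal length-M series, so the population correlation is ρ within a
  community and 0 across communities.

Neither generator attempts realistic BOLD hemodynamics, temporal
autocorrelation, or spatial smoothness; they exercise the engine's
arithmetic and ordering, not fMRI physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import TimeSeriesMatrix

__all__ = ["SynthSpec", "generate", "generate_uniform", "generate_planted",
           "community_labels"]

_RNG_ID = "pcg64"
UNIFORM_LOW, UNIFORM_HIGH = -6.0, 6.0


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset.

    kind="uniform" ignores the community fields; kind="planted" requires
    ``community_sizes`` summing to ``n_voxels`` and ρ in [0, 1).
    """

    n_voxels: int
    n_timepoints: int
    seed: int
    kind: str = "uniform"
    community_sizes: list[int] = field(default_factory=list)
    within_correlation_rho: float = 0.0

    def __post_init__(self):
        if self.n_voxels < 2 or self.n_timepoints < 2:
            raise ValueError(
                f"need n_voxels >= 2 and n_timepoints >= 2, got "
                f"{self.n_voxels} x {self.n_timepoints}"
            )
        if self.kind not in ("uniform", "planted"):
            raise ValueError(f"kind must be 'uniform' or 'planted', got {self.kind!r}")
        if self.kind == "planted":
            if not (0.0 <= self.within_correlation_rho < 1.0):
                raise ValueError(
                    f"within-community rho must be in [0, 1), got "
                    f"{self.within_correlation_rho}"
                )
            if not self.community_sizes or any(s < 1 for s in self.community_sizes):
                raise ValueError("community_sizes must be positive integers")
            if sum(self.community_sizes) != self.n_voxels:
                raise ValueError(
                    f"community sizes {self.community_sizes} sum to "
                    f"{sum(self.community_sizes)}, expected n_voxels={self.n_voxels}"
                )


def generate(spec: SynthSpec) -> TimeSeriesMatrix:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "uniform":
        return generate_uniform(spec)
    return generate_planted(spec)


def generate_uniform(spec: SynthSpec) -> TimeSeriesMatrix:
    """N×M i.i.d. uniform intensities on [−6, 6]; identical seed, identical matrix."""
    if spec.kind != "uniform":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'uniform'")
    rng = np.random.default_rng(spec.seed)
    values = rng.uniform(UNIFORM_LOW, UNIFORM_HIGH,
                         size=(spec.n_voxels, spec.n_timepoints))
    return TimeSeriesMatrix(
        values,
        voxel_order_tag=(
            f"synthetic:uniform(low={UNIFORM_LOW},high={UNIFORM_HIGH},"
            f"seed={spec.seed},rng={_RNG_ID})"
        ),
    )


def generate_planted(spec: SynthSpec) -> TimeSeriesMatrix:
    """Block-community Gaussian series with within-community correlation ρ."""
    if spec.kind != "planted":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'planted'")
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_correlation_rho
    m = spec.n_timepoints
    shared = rng.standard_normal((len(spec.community_sizes), m))
    noise = rng.standard_normal((spec.n_voxels, m))
    community = np.repeat(np.arange(len(spec.community_sizes)), spec.community_sizes)
    values = np.sqrt(rho) * shared[community] + np.sqrt(1.0 - rho) * noise
    return TimeSeriesMatrix(
        values,
        voxel_order_tag=(
            f"synthetic:planted(sizes={spec.community_sizes},rho={rho},"
            f"seed={spec.seed},rng={_RNG_ID})"
        ),
    )


def community_labels(spec: SynthSpec) -> np.ndarray:
    """Community label of each voxel row, in generation order."""
    if spec.kind != "planted":
        raise ValueError("community labels only exist for planted spectra")
    return np.repeat(np.arange(len(spec.community_sizes)), spec.community_sizes)
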