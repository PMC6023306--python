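"""Exception hierarchy.

Everything the package raises deliberately derives from ``VoxcorrError``
so callers (and the CLI) can distinguish our diagnostics from genuine bugs.
"""


class VoxcorrError(Exception):
    """Base class for all voxcorr errors."""


class DataError(VoxcorrError):
    """Input data is malformed: non-finite values, bad shapes, parse failures."""


class BudgetError(VoxcorrError):
    """The working-memory budget is too small for any feasible block plan."""


class BackendError(VoxcorrError):
    """A product backend failed; carries the identity of the round being run."""


class DegenerateVoxelError(DataError):
    """A constant time series was found under degenerate_policy='error'."""


class StoreCorruptionError(VoxcorrError):
    """An on-disk correlation store is inconsistent with its sidecar."""
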