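"""Input readers and the on-disk condensed-correlation store.

Three input layouts produce the same in-memory ``TimeSeriesMatrix``:

* delimited text — one voxel per line, whitespace- or comma-separated,
  no header by default;
* raw little-endian binary — a bare scalar array plus a JSON sidecar
  (``<file>.json``) carrying shape and dtype;
* 4-D NIfTI volume — optionally restricted by a 3-D mask on the same
  grid; voxels are flattened with the *first spatial axis varying
  fastest* (the dominant neuroimaging convention), and that convention is
  recorded in the matrix's order tag and in any store written from it.

The ``CorrelationStore`` persists a condensed array exactly as computed:
a raw little-endian data file (directly memory-mappable, no embedded
header) plus a JSON sidecar with the voxel count, precision, ordering
tag, degenerate-voxel record, the executed round trace, and an input
checksum. Random pair lookup is a single positioned read at the
condensed index of (min(i,j), max(i,j)).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np

from .engine import BlockPlan, BlockRound, CondensedCorrelationArray, TimeSeriesMatrix
from .errors import DataError, StoreCorruptionError
from .indexing import pair_to_linear, triangle_size

__all__ = [
    "read_matrix",
    "write_matrix",
    "CorrelationStore",
    "write_store",
    "open_store",
    "get_correlation",
    "matrix_checksum",
]

_DTYPES = {"f32": np.dtype("<f4"), "f64": np.dtype("<f8")}
_SIDECAR_SUFFIX = ".json"
FORMATS = ("delimited", "raw", "nifti")


def matrix_checksum(ts: TimeSeriesMatrix) -> str:
    """SHA-256 of the matrix values as little-endian float64 bytes."""
    buf = np.ascontiguousarray(ts.values, dtype="<f8")
    return hashlib.sha256(buf.tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# input readers


def detect_format(path) -> str:
    """Guess an input format from the file name."""
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".bin", ".raw", ".dat")):
        return "raw"
    return "delimited"


def read_matrix(
    path,
    format: str = "auto",
    mask=None,
    drop_degenerate: bool = False,
    header: bool = False,
) -> TimeSeriesMatrix:
    """Read voxel time series into an N×M matrix (voxels = rows).

    Parameters
    ----------
    path : path-like
        Input file. For ``raw``, a sidecar ``<path>.json`` with keys
        ``n_voxels``, ``n_timepoints``, ``dtype`` must sit next to it.
    format : "auto" | "delimited" | "raw" | "nifti"
        ``auto`` guesses from the extension.
    mask : path-like or 3-D array, optional
        For 4-D volumes only: keep voxels with a nonzero mask value. Must
        be congruent with the volume's spatial grid.
    drop_degenerate : bool
        Remove constant-series voxels before computation; their original
        indices are recorded in the order tag.
    header : bool
        Delimited input has one header line to skip.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if format == "auto":
        format = detect_format(path)
    if format == "delimited":
        ts = _read_delimited(path, header=header)
    elif format == "raw":
        ts = _read_raw(path)
    elif format == "nifti":
        ts = _read_volume(path, mask=mask)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if ts.n_voxels < 2:
        raise DataError(f"need at least 2 voxels, got {ts.n_voxels} from {path}")
    if ts.n_timepoints < 2:
        raise DataError(f"need at least 2 timepoints, got {ts.n_timepoints} from {path}")
    if drop_degenerate:
        ts = _drop_degenerate(ts)
    return ts


def _read_delimited(path: Path, header: bool) -> TimeSeriesMatrix:
    first_data = None
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first_data = line
                break
    if first_data is None:
        raise DataError(f"delimited file is empty: {path}")
    delimiter = "," if ("," in first_data) else None
    try:
        values = np.loadtxt(path, delimiter=delimiter, skiprows=1 if header else 0,
                            ndmin=2)
    except ValueError as exc:
        raise DataError(f"could not parse delimited matrix {path}: {exc}") from exc
    return TimeSeriesMatrix(values, voxel_order_tag=f"delimited:{path.name}")


def _read_raw(path: Path) -> TimeSeriesMatrix:
    sidecar = path.with_name(path.name + _SIDECAR_SUFFIX)
    if not sidecar.exists():
        raise DataError(f"raw binary input {path} is missing its sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        n, m = int(meta["n_voxels"]), int(meta["n_timepoints"])
        dtype = np.dtype(meta.get("dtype", "<f8")).newbyteorder("<")
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise DataError(f"bad raw-binary sidecar {sidecar}: {exc}") from exc
    expected = n * m * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise DataError(
            f"raw file {path} is {actual} bytes; sidecar implies "
            f"{n}x{m} {dtype.name} = {expected} bytes"
        )
    values = np.fromfile(path, dtype=dtype).reshape(n, m)
    return TimeSeriesMatrix(values, voxel_order_tag=f"raw:{path.name}")


def _read_volume(path: Path, mask=None) -> TimeSeriesMatrix:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise DataError(f"expected a 4-D volume, got {data.ndim}-D from {path}")
    nx, ny, nz, nt = data.shape
    # first spatial axis fastest: transpose spatial axes then C-flatten
    flat = data.transpose(2, 1, 0, 3).reshape(nx * ny * nz, nt)
    tag = f"volume:{Path(path).name}:x-fastest"
    if mask is not None:
        mvol = _load_mask(mask)
        if mvol.shape != (nx, ny, nz):
            raise DataError(
                f"mask shape {mvol.shape} does not match volume grid {(nx, ny, nz)}"
            )
        keep = mvol.transpose(2, 1, 0).ravel() != 0
        flat = flat[keep]
        tag += f":masked({int(keep.sum())} voxels)"
    return TimeSeriesMatrix(flat, voxel_order_tag=tag)


def _load_mask(mask) -> np.ndarray:
    if isinstance(mask, (str, Path)):
        return np.asanyarray(nib.load(str(mask)).dataobj)
    return np.asarray(mask)


def _drop_degenerate(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    centered = ts.values - ts.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    keep = norms > 1e-12 * np.sqrt(ts.n_timepoints)
    dropped = np.nonzero(~keep)[0]
    if not dropped.size:
        return ts
    return TimeSeriesMatrix(
        ts.values[keep],
        voxel_order_tag=f"{ts.voxel_order_tag}:dropped{dropped.tolist()}",
    )


def write_matrix(ts: TimeSeriesMatrix, path, format: str = "auto",
                 volume_shape=None) -> Path:
    """Write a time-series matrix in any layout :func:`read_matrix` accepts.

    For ``nifti``, ``volume_shape`` (X, Y, Z) with X·Y·Z = N is required;
    rows are unflattened with the first spatial axis fastest, the inverse
    of the reader's convention.
    """
    path = Path(path)
    if format == "auto":
        format = detect_format(path)
    if format == "delimited":
        np.savetxt(path, ts.values, fmt="%.17g")
    elif format == "raw":
        np.ascontiguousarray(ts.values, dtype="<f8").tofile(path)
        sidecar = {
            "n_voxels": ts.n_voxels,
            "n_timepoints": ts.n_timepoints,
            "dtype": "<f8",
            "byte_order": "little",
            "voxel_order_tag": ts.voxel_order_tag,
        }
        path.with_name(path.name + _SIDECAR_SUFFIX).write_text(
            json.dumps(sidecar, indent=1)
        )
    elif format == "nifti":
        if volume_shape is None or int(np.prod(volume_shape)) != ts.n_voxels:
            raise ValueError(
                f"nifti output needs volume_shape with product {ts.n_voxels}, "
                f"got {volume_shape}"
            )
        nx, ny, nz = (int(s) for s in volume_shape)
        vol = ts.values.reshape(nz, ny, nx, ts.n_timepoints).transpose(2, 1, 0, 3)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# the correlation store


@dataclass
class CorrelationStore:
    """A condensed correlation array on disk: raw data file + JSON sidecar."""

    data_path: Path
    meta: dict

    @property
    def n_voxels(self) -> int:
        return int(self.meta["n_voxels"])

    @property
    def precision(self) -> str:
        return self.meta["precision"]

    @property
    def dtype(self) -> np.dtype:
        return _DTYPES[self.precision]

    @property
    def sidecar_path(self) -> Path:
        return self.data_path.with_name(self.data_path.name + _SIDECAR_SUFFIX)

    def read_all(self) -> np.ndarray:
        """The full condensed array, bitwise as written."""
        return np.fromfile(self.data_path, dtype=self.dtype)

    def get_correlation(self, i: int, j: int) -> float:
        """Correlation of voxels (i, j) via one positioned read; (i, i) is 1
        by definition and is not stored."""
        n = self.n_voxels
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"voxel index out of range [0, {n}): ({i}, {j})")
        if i == j:
            return 1.0
        k = pair_to_linear(min(i, j), max(i, j), n)
        width = self.dtype.itemsize
        with open(self.data_path, "rb") as fh:
            fh.seek(k * width)
            buf = fh.read(width)
        if len(buf) != width:
            raise StoreCorruptionError(
                f"short read at pair ({i},{j}) (offset {k * width}) in {self.data_path}"
            )
        return float(np.frombuffer(buf, dtype=self.dtype)[0])


def write_store(
    c: CondensedCorrelationArray,
    plan: BlockPlan,
    path,
    n_timepoints: int | None = None,
    input_checksum: str | None = None,
    source: str | None = None,
) -> CorrelationStore:
    """Persist a condensed array and its provenance; round-trips bitwise."""
    path = Path(path)
    dtype = _DTYPES[c.precision]
    if len(c.values) != triangle_size(c.n_voxels):
        raise StoreCorruptionError(
            f"condensed array length {len(c.values)} != "
            f"triangle_size({c.n_voxels}) = {triangle_size(c.n_voxels)}"
        )
    np.ascontiguousarray(c.values, dtype=dtype).tofile(path)
    meta = {
        "format": "voxcorr-condensed-v1",
        "n_voxels": c.n_voxels,
        "n_timepoints": n_timepoints,
        "precision": c.precision,
        "order_tag": c.order_tag,
        "degenerate_policy": c.degenerate_policy,
        "degenerate_voxels": [int(v) for v in c.degenerate_voxels],
        "budget_elements": plan.budget_elements,
        "single_round": plan.single_round,
        "rounds": [
            {"start": r.start, "block_size": r.block_size, "remaining": r.remaining,
             "out_offset": r.out_offset, "out_length": r.out_length}
            for r in plan.rounds
        ],
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "source": source,
        "input_checksum": input_checksum,
    }
    store = CorrelationStore(data_path=path, meta=meta)
    store.sidecar_path.write_text(json.dumps(meta, indent=1))
    return store


def open_store(path) -> CorrelationStore:
    """Open an existing store, validating sidecar/data consistency."""
    path = Path(path)
    sidecar = path.with_name(path.name + _SIDECAR_SUFFIX)
    if not path.exists():
        raise StoreCorruptionError(f"store data file not found: {path}")
    if not sidecar.exists():
        raise StoreCorruptionError(f"store sidecar not found: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise StoreCorruptionError(f"unreadable sidecar {sidecar}: {exc}") from exc
    for key in ("n_voxels", "precision", "order_tag", "rounds"):
        if key not in meta:
            raise StoreCorruptionError(f"sidecar {sidecar} is missing {key!r}")
    n = int(meta["n_voxels"])
    t = triangle_size(n)
    if meta["precision"] not in _DTYPES:
        raise StoreCorruptionError(f"unknown precision {meta['precision']!r} in sidecar")
    expected = t * _DTYPES[meta["precision"]].itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise StoreCorruptionError(
            f"store {path} holds {actual} bytes; sidecar implies "
            f"{t} x {_DTYPES[meta['precision']].name} = {expected} bytes"
        )
    if sum(r["out_length"] for r in meta["rounds"]) != t:
        raise StoreCorruptionError(
            f"sidecar round trace of {sidecar} does not tile the triangle"
        )
    return CorrelationStore(data_path=path, meta=meta)


def get_correlation(store: CorrelationStore, i: int, j: int) -> float:
    """Module-level convenience alias for :meth:`CorrelationStore.get_correlation`."""
    return store.get_correlation(i, j)
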