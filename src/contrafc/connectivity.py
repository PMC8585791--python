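"""Whole-brain ROI x ROI Pearson connectivity matrices.

A subject's scan may comprise several runs; retained frames of all runs are
concatenated and a single Pearson correlation matrix is computed over them in
the canonical ROI order.  Raw Pearson r is used throughout — no Fisher z
transform.  An optional helper extracts ROI mean time series from a 4-D
volumetric image using spherical masks around the atlas coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import ROITable
from .errors import ValidationError, ZeroVarianceError
from .preprocess import TimeSeriesRun, make_run

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson r matrix over a stated ROI order.

    Invariants: symmetric to 1e-12, unit diagonal, entries in [-1, 1],
    dimension equal to the length of ``roi_ids``.
    """

    values: np.ndarray
    roi_ids: tuple[str, ...]
    n_frames_used: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.roi_ids)
        if values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {n} ROI ids"
            )
        if n and not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValidationError("connectivity matrix is not symmetric")
        if n and not np.allclose(np.diag(values), 1.0, atol=_SYMMETRY_TOL, rtol=0):
            raise ValidationError("connectivity matrix diagonal is not unit")
        if n and (np.min(values) < -1 - 1e-9 or np.max(values) > 1 + 1e-9):
            raise ValidationError("connectivity entries outside [-1, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))

    @property
    def n(self) -> int:
        return len(self.roi_ids)


def correlation_matrix(runs: Sequence[TimeSeriesRun],
                       roi_ids: Sequence[str]) -> ConnectivityMatrix:
    """Pearson correlation matrix over the concatenated retained frames.

    All runs must share the ROI count given by ``roi_ids`` (canonical order).
    Censored frames contribute nothing.  A constant ROI is a hard error —
    silent NaNs would corrupt the downstream matrix statistic.
    """
    if len(runs) == 0:
        raise ValidationError("no runs supplied")
    n_rois = len(roi_ids)
    blocks = []
    for run in runs:
        if run.n_rois != n_rois:
            raise ValidationError(
                f"run {run.run_id!r} has {run.n_rois} ROIs, expected {n_rois}"
            )
        blocks.append(run.data[run.censor_mask])
    data = np.concatenate(blocks, axis=0)
    n_frames = data.shape[0]
    if n_frames < 3:
        raise ValidationError(
            f"only {n_frames} retained frames in total; need at least 3"
        )
    sd = data.std(axis=0)
    # relative tolerance: an exactly-constant column has std ~ 1 ulp of its mean
    flat = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(data).mean(axis=0)))
    if flat.size:
        names = ", ".join(repr(roi_ids[i]) for i in flat[:5])
        raise ZeroVarianceError(
            f"ROI series constant across retained frames: {names}"
        )
    values = np.corrcoef(data, rowvar=False)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values=values, roi_ids=tuple(roi_ids),
                              n_frames_used=n_frames)


def extract_roi_timeseries(image, table: ROITable, radius_mm: float = 5.0,
                           run_id: str = "") -> TimeSeriesRun:
    """Mean time series within a sphere around each ROI centre of a 4-D image.

    ``image`` is a nibabel spatial image (or a path to one); its affine maps
    voxel indices to millimetre coordinates in the same space as the ROI
    table.  Each ROI series is the per-frame mean of all voxels within
    ``radius_mm`` of the ROI centre.  TR is taken from the image header
    zooms (fourth zoom), falling back to 1.0 s when absent.
    """
    import nibabel as nib

    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = nib.load(image)
    if radius_mm <= 0:
        raise ValidationError("radius_mm must be positive")
    data = np.asanyarray(image.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D image, got {data.ndim}-D")
    nx, ny, nz, n_frames = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    affine = image.affine
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    flat = data.reshape(-1, n_frames)

    zooms = getattr(image.header, "get_zooms", lambda: ())()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0

    r2 = float(radius_mm) ** 2
    series = np.empty((n_frames, len(table)), dtype=float)
    for j, rec in enumerate(table):
        centre = np.array([rec.x, rec.y, rec.z])
        d2 = np.sum((mm - centre) ** 2, axis=1)
        inside = d2 <= r2
        if not inside.any():
            raise ValidationError(
                f"ROI {rec.roi_id!r}: no voxels within {radius_mm} mm of "
                f"({rec.x}, {rec.y}, {rec.z})"
            )
        series[:, j] = flat[inside].mean(axis=0)
    return make_run(series, tr_seconds=tr, run_id=run_id)


def write_matrix_tsv(matrix: ConnectivityMatrix, path, sidecar: dict | None = None) -> None:
    """Write a square matrix as TSV with roi_id header row/column, plus a
    JSON side-car recording ``n_frames_used`` and any extra parameters."""
    frame = pd.DataFrame(matrix.values, index=matrix.roi_ids,
                         columns=matrix.roi_ids)
    frame.to_csv(path, sep="\t", index_label="roi_id", float_format="%.10g")
    meta = {"n_frames_used": matrix.n_frames_used, "n_rois": matrix.n}
    if sidecar:
        meta.update(sidecar)
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_matrix_tsv(path) -> ConnectivityMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    # symmetrize away text round-off, then let the constructor validate
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    n_frames = 0
    try:
        with open(f"{path}.json") as fh:
            n_frames = int(json.load(fh).get("n_frames_used", 0))
    except (OSError, ValueError):
        pass
    return ConnectivityMatrix(values=values,
                              roi_ids=tuple(str(c) for c in frame.columns),
                              n_frames_used=n_frames)


def write_timeseries_tsv(run: TimeSeriesRun, roi_ids: Sequence[str], path) -> None:
    """One row per frame, one column per ROI, header = roi ids."""
    frame = pd.DataFrame(run.data, columns=list(roi_ids))
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, tr_seconds: float, run_id: str = "") -> TimeSeriesRun:
    frame = pd.read_csv(path, sep="\t")
    return make_run(frame.to_numpy(dtype=float), tr_seconds=tr_seconds,
                    run_id=run_id or str(path))
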