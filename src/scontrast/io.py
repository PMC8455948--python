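"""Reading and writing of 4D BOLD volumes, masks, regressor tables and metric maps.

The two containers defined here, :class:`Bold4D` and :class:`MetricMap`, are
the currency of the whole package: every analysis consumes a masked 4D scan
and produces one or more 3D scalar maps with provenance attached.

Conventions
-----------
* Volume discard is explicit (default 10 dummy volumes), never silent.
* The automatic brain mask keeps voxels with nonzero temporal standard
  deviation; constant voxels make every spectral metric degenerate.
* Missing values inside maps are NaN, the standard sentinel for
  statistical images.
* Regressor tables must already match the retained volumes row-for-row;
  rows are never re-aligned silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Bold4D",
    "MetricMap",
    "load_bold",
    "load_mask",
    "load_regressors",
    "save_map",
    "load_map",
    "automatic_mask",
]

MISSING = np.nan
DEFAULT_DISCARD = 10


def automatic_mask(data: np.ndarray) -> np.ndarray:
    """Voxels with nonzero temporal standard deviation.

    Zero-variance voxels (air, padding) have an empty spectrum and would be
    degenerate under every metric, so they are excluded up front.
    """
    if data.ndim != 4:
        raise ValueError(f"expected 4D data, got {data.ndim}D")
    return np.nanstd(data, axis=-1) > 0


@dataclass
class Bold4D:
    """A masked 4D BOLD scan: voxel time courses plus sampling interval.

    Parameters
    ----------
    data:
        4D array (x, y, z, t) in arbitrary BOLD units.
    tr:
        Repetition time (sampling interval) in seconds. Must be positive.
    mask:
        3D boolean array selecting the voxels to analyse. If None, the
        automatic nonzero-variance mask is used.
    spatial_meta:
        Affine / orientation metadata carried opaquely from input to output.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray | None = None
    spatial_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D requires 4D data, got {self.data.ndim}D")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_volumes < 8:
            raise ValueError(
                f"need at least 8 time points, got {self.n_volumes}"
            )
        if self.mask is None:
            self.mask = automatic_mask(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.spatial_shape}"
            )
        if not self.mask.any():
            raise ValueError("mask selects no voxels")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the mask")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        """Highest resolvable frequency, 1/(2*tr), in Hz."""
        return 1.0 / (2.0 * self.tr)

    @property
    def affine(self) -> np.ndarray:
        return np.asarray(self.spatial_meta.get("affine", np.eye(4)))

    def masked_series(self) -> np.ndarray:
        """In-mask voxel time courses as an (n_voxels, T) array."""
        return self.data[self.mask]


@dataclass
class MetricMap:
    """A 3D scalar map (SCM, ALFF, z-score, test statistic, ...).

    ``params`` records everything that produced the map; the same Bold4D
    and params always reproduce identical values. Voxels outside the mask
    hold NaN.
    """

    values: np.ndarray
    mask: np.ndarray
    metric_name: str
    params: dict[str, Any] = field(default_factory=dict)
    spatial_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"MetricMap values must be 3D, got {self.values.ndim}D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        self.values = np.where(self.mask, self.values, MISSING)

    @property
    def affine(self) -> np.ndarray:
        return np.asarray(self.spatial_meta.get("affine", np.eye(4)))

    def finite_mask(self) -> np.ndarray:
        """In-mask voxels that carry a non-missing value."""
        return self.mask & np.isfinite(self.values)

    def in_mask_values(self) -> np.ndarray:
        """Non-missing in-mask values as a 1D vector."""
        return self.values[self.finite_mask()]


def load_bold(
    path: str | Path,
    tr: float | str = "from header",
    discard: int = DEFAULT_DISCARD,
    mask: np.ndarray | None = None,
) -> Bold4D:
    """Load a 4D NIfTI-1 file, dropping the first ``discard`` volumes.

    ``tr="from header"`` reads pixdim[4]; an explicit float overrides the
    header (useful when the header zoom is wrong or zero).
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {img.ndim}D")
    if discard < 0:
        raise ValueError(f"discard must be nonnegative, got {discard}")
    n_vols = img.shape[3]
    if discard >= n_vols:
        raise ValueError(
            f"discard={discard} leaves no volumes (file has {n_vols})"
        )
    if tr == "from header":
        zooms = img.header.get_zooms()
        tr_val = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr_val > 0:
            raise ValueError(
                f"{path}: header pixdim[4]={tr_val} is not a valid TR; "
                "pass tr explicitly"
            )
    else:
        tr_val = float(tr)
        if not tr_val > 0:
            raise ValueError(f"tr must be positive, got {tr_val}")
    data = np.asarray(img.get_fdata(dtype=np.float64))[..., discard:]
    meta = {"affine": np.asarray(img.affine), "source": str(path), "discard": discard}
    return Bold4D(data=data, tr=tr_val, mask=mask, spatial_meta=meta)


def load_mask(path: str | Path | None, reference: Bold4D) -> np.ndarray:
    """Load a 3D mask matching ``reference``; automatic mask when path is None.

    Any nonzero voxel is included. The automatic mask keeps voxels with
    nonzero temporal standard deviation.
    """
    if path is None:
        return automatic_mask(reference.data)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D, got {img.ndim}D")
    if img.shape != reference.spatial_shape:
        raise ValueError(
            f"{path}: mask shape {img.shape} does not match data "
            f"{reference.spatial_shape}"
        )
    return np.asarray(img.get_fdata()) != 0


def load_regressors(
    path: str | Path,
    expected_rows: int,
    header: bool | str = "auto",
) -> np.ndarray:
    """Read a TSV of nuisance regressors as a (T, R) float matrix.

    The file must have exactly one row per *retained* volume: if dummy
    volumes were discarded from the BOLD series, the caller must supply a
    table already truncated to match. ``header`` may be True, False or
    "auto" (sniff whether the first row parses as numbers).
    """
    if header == "auto":
        first = pd.read_csv(path, sep="\t", header=None, nrows=1)
        try:
            first.astype(float)
            header = False
        except (ValueError, TypeError):
            header = True
    df = pd.read_csv(path, sep="\t", header=0 if header else None)
    try:
        mat = df.to_numpy(dtype=np.float64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric value in regressor table: {exc}")
    if not np.isfinite(mat).all():
        raise ValueError(f"{path}: non-finite value in regressor table")
    if mat.shape[0] != expected_rows:
        raise ValueError(
            f"{path}: {mat.shape[0]} rows but {expected_rows} retained "
            "volumes; regressors must be truncated to match discarded volumes"
        )
    return mat


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_map(metric_map: MetricMap, path: str | Path) -> None:
    """Write a MetricMap as 3D NIfTI plus a JSON provenance sidecar.

    Out-of-mask voxels are stored as NaN; a round-trip load reproduces the
    in-mask values bit-exactly (data are stored as float64).
    """
    img = nib.Nifti1Image(metric_map.values.astype(np.float64), metric_map.affine)
    nib.save(img, str(path))
    sidecar = {
        "metric_name": metric_map.metric_name,
        "params": _jsonable(metric_map.params),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_map(path: str | Path, mask: np.ndarray | None = None) -> MetricMap:
    """Load a 3D map saved by :func:`save_map`, restoring sidecar metadata."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {img.ndim}D")
    values = np.asarray(img.get_fdata(dtype=np.float64))
    sidecar = _sidecar_path(path)
    metric_name, params = "unknown", {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        metric_name = meta.get("metric_name", "unknown")
        params = meta.get("params", {})
    if mask is None:
        mask = np.isfinite(values)
        if not mask.any():
            mask = np.ones(values.shape, dtype=bool)
    return MetricMap(
        values=values,
        mask=mask,
        metric_name=metric_name,
        params=params,
        spatial_meta={"affine": np.asarray(img.affine), "source": str(path)},
    )
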