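"""Hyperspectral cube containers, readers/writers and preprocessing.

A :class:`HyperCube` is one tissue sample's rank-3 image ``(rows, cols,
bands)`` with a strictly increasing NIR wavelength vector (nanometres) and
an optional binary label (0 = non-cancer, 1 = cancer).

Two on-disk dialects are supported:

* multi-page TIFF, one band per page, page order = band order; wavelengths
  and label travel in a JSON payload inside the first page's
  ImageDescription tag, with a plain-text sidecar
  ``<stem>.wavelengths.txt`` as fallback;
* an ``.npz`` container with keys ``data``, ``wavelengths`` and optionally
  ``label`` / ``sample_id``.

Preprocessing follows the acquisition pipeline's two steps: per-cube
min-max scaling to [0, 1], then clipping to mean +/- 5 SD to suppress
extreme spectra from measurement artifacts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

from .errors import (
    BandMismatchError,
    ManifestError,
    MissingFileError,
    NonFiniteDataError,
    RaggedPageShapeError,
)

__all__ = [
    "HyperCube",
    "CohortManifest",
    "read_cube",
    "write_cube",
    "minmax_normalize",
    "clip_extremes",
    "spectra_count",
    "preprocess",
    "read_manifest",
    "write_manifest",
]

#: default NIR window of the imaging system, nanometres
NIR_RANGE = (1000.0, 1750.0)


@dataclass
class HyperCube:
    """One sample's hyperspectral image plus metadata.

    Attributes
    ----------
    sample_id : str
        Unique identifier within a cohort.
    data : ndarray, shape (rows, cols, bands)
        Non-negative counts before normalization; float32 internally.
    wavelengths : ndarray, shape (bands,)
        Strictly increasing, nanometres.
    label : int or None
        0 = non-cancer, 1 = cancer, None = unlabeled.
    meta : dict
        Free-form annotations (age, sex, generator ground truth, ...).
    """

    sample_id: str
    data: np.ndarray
    wavelengths: np.ndarray
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise BandMismatchError(
                f"cube data must have 3 axes, got {self.data.ndim}"
            )
        if self.data.shape[2] != self.wavelengths.shape[0]:
            raise BandMismatchError(
                f"band axis length {self.data.shape[2]} != "
                f"wavelength count {self.wavelengths.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise NonFiniteDataError(
                f"cube {self.sample_id!r} contains NaN/Inf voxels"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise BandMismatchError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "HyperCube":
        return HyperCube(
            self.sample_id,
            self.data.copy(),
            self.wavelengths.copy(),
            self.label,
            dict(self.meta),
        )


@dataclass
class CohortManifest:
    """Cohort table: one record per sample (id, path, label, meta)."""

    records: list[dict]

    def __post_init__(self) -> None:
        ids = [r["sample_id"] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate sample_id in manifest")
        for r in self.records:
            lab = r.get("label")
            if lab is not None and int(lab) not in (0, 1):
                raise ManifestError(f"label {lab!r} not in {{0, 1}}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[dict]:
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r["sample_id"] for r in self.records]


def spectra_count(cube: HyperCube) -> int:
    """Number of spatial spectra in the cube (rows x cols).

    A 600 x 450 acquisition yields 270,000 spectra per tissue sample.
    """
    return int(cube.data.shape[0] * cube.data.shape[1])


def minmax_normalize(cube: HyperCube) -> HyperCube:
    """Scale all voxels of the cube to [0, 1] by a single affine map.

    The normalization is per cube over all voxels (not per band), so a
    cube-wide illumination/detector gain cancels. A constant cube maps to
    all zeros (declared degenerate-case convention).
    """
    x = cube.data
    if not np.all(np.isfinite(x)):
        raise NonFiniteDataError("cannot normalize non-finite cube")
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    new = cube.copy()
    new.data = out.astype(np.float32)
    new.meta["normalized"] = True
    return new

def clip_extremes(
    cube: HyperCube, k_sd: float = 5.0, scope: str = "cube"
) -> HyperCube:
    """Clip voxels to mean +/- ``k_sd`` standard deviations.

    Applied after min-max scaling; removes extreme spectral values from
    measurement artifacts while leaving in-band voxels untouched.

    Parameters
    ----------
    scope : {"cube", "pixel"}
        "cube" pools mean/SD over all voxels (default); "pixel" computes
        them per spatial spectrum along the band axis.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    x = cube.data.astype(np.float64)
    if scope == "cube":
        m, s = x.mean(), x.std()
        if s == 0:
            return cube.copy()
        out = np.clip(x, m - k_sd * s, m + k_sd * s)
    elif scope == "pixel":
        m = x.mean(axis=2, keepdims=True)
        s = x.std(axis=2, keepdims=True)
        s_safe = np.where(s == 0, 1.0, s)
        out = np.clip(x, m - k_sd * s_safe, m + k_sd * s_safe)
        out = np.where(s == 0, x, out)
    else:
        raise ValueError(f"unknown clip scope {scope!r}")
    new = cube.copy()
    new.data = out.astype(np.float32)
    new.meta["clipped_k_sd"] = k_sd
    return new


def preprocess(cube: HyperCube, k_sd: float = 5.0, scope: str = "cube") -> HyperCube:
    """Min-max normalize then SD-clip, in the acquisition pipeline's order."""
    return clip_extremes(minmax_normalize(cube), k_sd=k_sd, scope=scope)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SIDE_SUFFIX = ".wavelengths.txt"


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".tif", ".tiff"):
        return "tiff"
    if path.suffix.lower() == ".npz":
        return "npz"
    raise ValueError(f"cannot infer cube format from suffix {path.suffix!r}")


def write_cube(cube: HyperCube, path: str | Path, format: str | None = None) -> Path:
    """Write a cube as band-per-page TIFF or as an npz container."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        desc = json.dumps(
            {
                "sample_id": cube.sample_id,
                "wavelengths": cube.wavelengths.tolist(),
                "label": cube.label,
            }
        )
        pages = np.moveaxis(cube.data, 2, 0)  # (bands, rows, cols)
        tifffile.imwrite(
            path, pages, description=desc, photometric="minisblack", planarconfig=None
        )
    elif fmt == "npz":
        extra = {}
        if cube.label is not None:
            extra["label"] = np.int64(cube.label)
        np.savez_compressed(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            sample_id=np.str_(cube.sample_id),
            **extra,
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_cube(path: str | Path, format: str | None = None) -> HyperCube:
    """Read a cube from TIFF (band per page) or npz.

    Raises
    ------
    MissingFileError, RaggedPageShapeError, BandMismatchError,
    NonFiniteDataError
        One named error per contract violation.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        return _read_tiff(path)
    if fmt == "npz":
        return _read_npz(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_tiff(path: Path) -> HyperCube:
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise RaggedPageShapeError(
                f"{path}: page shapes differ: {sorted(shapes)}"
            )
        pages = np.stack([p.asarray() for p in tf.pages])
        desc = tf.pages[0].description
    data = np.moveaxis(pages, 0, 2)
    b = data.shape[2]
    sample_id = path.stem
    label = None
    wavelengths = None
    if desc:
        try:
            info = json.loads(desc)
            sample_id = info.get("sample_id", sample_id)
            label = info.get("label")
            if "wavelengths" in info:
                wavelengths = np.asarray(info["wavelengths"], dtype=float)
        except (json.JSONDecodeError, TypeError):
            pass
    if wavelengths is None:
        sidecar = Path(str(path.with_suffix("")) + _SIDE_SUFFIX)
        if sidecar.exists():
            wavelengths = np.loadtxt(sidecar, ndmin=1)
        else:
            wavelengths = np.linspace(*NIR_RANGE, b)
    if wavelengths.shape[0] != b:
        raise BandMismatchError(
            f"{path}: {b} pages but {wavelengths.shape[0]} wavelengths"
        )
    if not np.all(np.isfinite(data)):
        raise NonFiniteDataError(f"{path}: NaN/Inf content")
    return HyperCube(sample_id, data, wavelengths, label)


def _read_npz(path: Path) -> HyperCube:
    with np.load(path, allow_pickle=False) as z:
        if "data" not in z or "wavelengths" not in z:
            raise BandMismatchError(
                f"{path}: container must hold 'data' and 'wavelengths'"
            )
        data = z["data"]
        wavelengths = z["wavelengths"]
        label = int(z["label"]) if "label" in z else None
        sample_id = str(z["sample_id"]) if "sample_id" in z else path.stem
    if data.ndim != 3 or data.shape[2] != wavelengths.shape[0]:
        raise BandMismatchError(
            f"{path}: data shape {data.shape} vs {wavelengths.shape[0]} wavelengths"
        )
    if not np.all(np.isfinite(data)):
        raise NonFiniteDataError(f"{path}: NaN/Inf content")
    return HyperCube(sample_id, data, wavelengths, label)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "path", "label"])
        for r in manifest.records:
            lab = r.get("label")
            w.writerow([r["sample_id"], r.get("path", ""), "" if lab is None else lab])
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lab = row.get("label", "")
            records.append(
                {
                    "sample_id": row["sample_id"],
                    "path": row.get("path", ""),
                    "label": int(lab) if lab not in ("", None) else None,
                }
            )
    return CohortManifest(records)
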