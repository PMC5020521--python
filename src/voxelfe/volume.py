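"""Calibrated 3-D density and label volumes.

The in-memory containers for the whole pipeline.  A :class:`DensityVolume`
holds a density-calibrated image (mg HA/cm^3) on an isotropic voxel grid,
axis order ``(x, y, z)`` with ``z`` the axial (slice) direction.  Slice
index 0 is the distal end of the scanned region.  Volumes round-trip
through NIfTI-1 (via nibabel) and the plain-text-header MetaImage format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

# Label coding used on disk (uint8) and in memory.
VOID = 0
TRAB = 1
CORT = 2

DEFAULT_VOXEL_SIZE = 0.082  # mm, isotropic


@dataclass
class DensityVolume:
    """A calibrated density image.

    Parameters
    ----------
    data:
        3-D float array of densities in mg HA/cm^3, axes ``(x, y, z)``.
    voxel_size:
        Isotropic voxel edge length in mm.
    site:
        One of ``radius``, ``tibia``, ``phantom``.
    scan_id:
        Free-text identifier (participant/time-point).
    """

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    site: str = "phantom"
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density volume must be 3-D with positive extents")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density volume contains non-finite values")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self, **changes) -> "DensityVolume":
        out = replace(self, data=self.data.copy())
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | os.PathLike) -> None:
        save_volume(self.data, self.voxel_size, path)

    @classmethod
    def load(cls, path: str | os.PathLike, site: str = "phantom",
             scan_id: str = "") -> "DensityVolume":
        data, voxel = load_volume(path)
        return cls(data=data.astype(np.float32), voxel_size=voxel,
                   site=site, scan_id=scan_id)


@dataclass
class LabelVolume:
    """Per-voxel tissue labels: VOID=0, TRAB=1, CORT=2."""

    labels: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    provenance: str = ""
    site: str = "phantom"
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.isin(self.labels, (VOID, TRAB, CORT)).all():
            raise ValueError("labels must be in {VOID, TRAB, CORT}")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]

    @property
    def bone(self) -> np.ndarray:
        return self.labels != VOID

    def save(self, path: str | os.PathLike) -> None:
        save_volume(self.labels, self.voxel_size, path)

    @classmethod
    def load(cls, path: str | os.PathLike, **kw) -> "LabelVolume":
        data, voxel = load_volume(path)
        return cls(labels=np.rint(data).astype(np.uint8), voxel_size=voxel, **kw)


# ---------------------------------------------------------------------------
# File formats: NIfTI-1 through nibabel; MetaImage (.mhd + .raw) written by a
# minimal reader/writer (the header is a handful of "Key = value" lines).

def save_volume(data: np.ndarray, voxel_size: float,
                path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms((voxel_size,) * 3)
        nib.save(img, path)
    elif path.endswith(".mhd"):
        _save_metaimage(np.asarray(data), voxel_size, path)
    else:
        raise ValueError(f"unsupported volume format: {path}")


def load_volume(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        voxel = float(img.header.get_zooms()[0])
        return np.asarray(img.dataobj), voxel
    if path.endswith(".mhd"):
        return _load_metaimage(path)
    raise ValueError(f"unsupported volume format: {path}")


_MET_TYPES = {
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
    "MET_UCHAR": np.uint8, "MET_SHORT": np.int16, "MET_INT": np.int32,
}


def _save_metaimage(data: np.ndarray, voxel_size: float, path: str) -> None:
    raw_path = path[:-4] + ".raw"
    met_type = {v: k for k, v in _MET_TYPES.items()}.get(data.dtype.type)
    if met_type is None:
        data = data.astype(np.float32)
        met_type = "MET_FLOAT"
    nx, ny, nz = data.shape
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        f"DimSize = {nx} {ny} {nz}",
        f"ElementSpacing = {voxel_size} {voxel_size} {voxel_size}",
        f"ElementType = {met_type}",
        f"ElementDataFile = {os.path.basename(raw_path)}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
    # MetaImage raw layout is x-fastest; Fortran order preserves our axes.
    data.ravel(order="F").tofile(raw_path)


def _load_metaimage(path: str) -> tuple[np.ndarray, float]:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                fields[k.strip()] = v.strip()
    shape = tuple(int(t) for t in fields["DimSize"].split())
    spacing = float(fields["ElementSpacing"].split()[0])
    dtype = _MET_TYPES[fields["ElementType"]]
    raw_path = os.path.join(os.path.dirname(path), fields["ElementDataFile"])
    data = np.fromfile(raw_path, dtype=dtype).reshape(shape, order="F")
    return data, spacing
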