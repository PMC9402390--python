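"""NIfTI volume input/output and geometric canonicalization.

All downstream stages consume volumes in one canonical right-handed
orientation (RAS+: first axis left→right, second posterior→anterior, third
inferior→superior).  Anatomical plane names are defined relative to that
convention: *axial* slices are taken along the third (S) axis, *coronal*
along the second (A) axis, and *sagittal* along the first (R) axis.

Voxel indices are 0-based throughout the codebase; physical quantities are
expressed in mm (spacing) and ml (volumes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConsistencyError, DimensionalityError, GeometryError

__all__ = [
    "CANONICAL_ORIENTATION",
    "VolumeImage",
    "BinaryMask",
    "Parcellation",
    "read_volume",
    "read_mask",
    "read_parcellation",
    "write_volume",
    "write_parcellation",
    "canonicalize",
    "voxel_volume_ml",
    "geometry_equal",
    "require_same_geometry",
]

#: Canonical axis labeling all stages assume after :func:`canonicalize`.
CANONICAL_ORIENTATION = "RAS"


def _validate_geometry(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise DimensionalityError(
            f"expected a 3D volume, got shape {tuple(data.shape)}"
        )
    if min(data.shape) < 1:
        raise DimensionalityError(f"every axis must have length >= 1, got {data.shape}")
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    spacing = nib.affines.voxel_sizes(affine)
    if not np.all(spacing > 0):
        raise GeometryError(f"voxel spacing must be positive, got {tuple(spacing)}")


@dataclass
class VolumeImage:
    """A 3D scalar field with physical geometry.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    affine
        4x4 voxel-to-world map; voxel spacing in mm is derived from it.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_geometry(self.data, self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel edge lengths in mm."""
        return tuple(float(s) for s in nib.affines.voxel_sizes(self.affine))  # type: ignore[return-value]

    @property
    def orientation_tag(self) -> str:
        """Axis codes of the affine, e.g. ``'RAS'``."""
        return "".join(nib.aff2axcodes(self.affine))


@dataclass
class BinaryMask:
    """A 3D {0,1} field sharing a :class:`VolumeImage`'s geometry."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_geometry(self.data, self.affine)

    shape = VolumeImage.shape
    spacing = VolumeImage.spacing
    orientation_tag = VolumeImage.orientation_tag

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class Parcellation:
    """A 3D non-negative integer label field plus label→region-name map.

    Label 0 is background by convention and never appears in ``labels``.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("parcellation values must be integers")
            arr = rounded
        if arr.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        self.data = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_geometry(self.data, self.affine)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"labels present in data but unnamed: {sorted(missing)}")

    shape = VolumeImage.shape
    spacing = VolumeImage.spacing
    orientation_tag = VolumeImage.orientation_tag


Geometric = VolumeImage | BinaryMask | Parcellation


def geometry_equal(a: Geometric, b: Geometric, atol: float = 1e-4) -> bool:
    """True when two objects live on the same grid in the same world frame."""
    return a.data.shape == b.data.shape and np.allclose(a.affine, b.affine, atol=atol)


def require_same_geometry(a: Geometric, b: Geometric, what: str = "inputs") -> None:
    if not geometry_equal(a, b):
        raise ConsistencyError(
            f"{what} must share geometry: shapes {a.data.shape} vs {b.data.shape}, "
            f"affines differ by {np.abs(np.asarray(a.affine) - np.asarray(b.affine)).max():.3g}"
        )


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI file as a :class:`VolumeImage`.

    No intensity rescaling beyond the NIfTI header's own scl slope/intercept
    is applied.  4D images (time series) are rejected.
    """
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got shape {tuple(shape)}"
        )
    data = np.asarray(img.get_fdata(dtype=np.float32))
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI binary mask; values must round to {0,1}."""
    vol = read_volume(path)
    rounded = np.rint(vol.data)
    if not np.allclose(vol.data, rounded, atol=1e-3):
        raise ValueError(f"{path}: mask contains non-binary values")
    return BinaryMask(data=rounded.astype(np.uint8), affine=vol.affine)


def read_parcellation(path: str | Path, labels_path: str | Path | None = None) -> Parcellation:
    """Read an integer label volume plus an optional JSON label→name map.

    Without ``labels_path`` every nonzero label k is named ``region_k``.
    """
    vol = read_volume(path)
    data = np.rint(vol.data).astype(np.int32)
    if labels_path is not None:
        with open(labels_path) as fh:
            raw = json.load(fh)
        labels = {int(k): str(v) for k, v in raw.items()}
    else:
        labels = {int(k): f"region_{int(k)}" for k in np.unique(data) if k != 0}
    return Parcellation(data=data, affine=vol.affine, labels=labels)


def write_volume(vol: Geometric, path: str | Path) -> None:
    """Write a volume/mask/parcellation to NIfTI.

    Masks and parcellations are stored with integer datatypes; images as
    float32.  Round-trips through :func:`read_volume`/:func:`read_mask` are
    exact on data and spacing.
    """
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, Parcellation):
        data = vol.data.astype(np.int16 if vol.data.max() < 2**15 else np.int32)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(data.dtype)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # unwritable path → I/O error with context
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def write_parcellation(parc: Parcellation, path: str | Path,
                       labels_path: str | Path | None = None) -> None:
    """Write a parcellation volume and (optionally) its JSON label map."""
    write_volume(parc, path)
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            json.dump({str(k): v for k, v in parc.labels.items()}, fh, indent=1)


def canonicalize(vol: Geometric) -> Geometric:
    """Permute/flip axes into the canonical RAS+ convention.

    The affine is updated so that the world coordinates of every voxel are
    unchanged; the operation is a pure re-indexing (the multiset of voxel
    values is preserved) and is idempotent.
    """
    affine = np.asarray(vol.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine rotation block is singular; cannot orient volume")
    ornt = nib.orientations.io_orientation(affine)
    if np.allclose(ornt, [[0, 1], [1, 1], [2, 1]]):
        return vol  # already canonical
    data = nib.orientations.apply_orientation(vol.data, ornt)
    new_affine = affine @ nib.orientations.inv_ornt_aff(ornt, vol.data.shape)
    if isinstance(vol, Parcellation):
        return Parcellation(data=data, affine=new_affine, labels=dict(vol.labels))
    return type(vol)(data=data, affine=new_affine)


def voxel_volume_ml(vol: Geometric) -> float:
    """Volume of a single voxel in ml (product of spacings / 1000)."""
    return float(np.prod(vol.spacing)) / 1000.0
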