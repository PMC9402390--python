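"""Intensity normalization and 3D↔2D slice-stack conversion.

A volume is normalized per-volume to [0, 1], then cut into ordered 2D slices
along one anatomical plane; each slice is zero-padded to square about its
center (preserving aspect ratio) and linearly resampled to the network
resolution.  The per-slice transform log makes the mapping exactly invertible
in shape, so per-slice predictions can be reassembled onto the original grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConsistencyError
from .volume_io import BinaryMask, VolumeImage

__all__ = [
    "PLANES",
    "PLANE_AXES",
    "SliceStack",
    "normalize_intensity",
    "extract_slices",
    "extract_mask_slices",
    "reassemble",
    "export_png",
]

#: Slicing axis for each anatomical plane, in the canonical RAS+ convention.
PLANE_AXES = {"axial": 2, "coronal": 1, "sagittal": 0}
PLANES = tuple(PLANE_AXES)


@dataclass
class SliceTransform:
    """Shape bookkeeping for one slice: original in-plane dims, pad offsets,
    padded square size, and the resize factor square→network resolution."""

    orig_shape: tuple[int, int]
    pad_before: tuple[int, int]
    square: int
    scale: float


@dataclass
class SliceStack:
    """Ordered 2D slices of one anatomical plane at network resolution."""

    plane: str
    slices: np.ndarray  # (n_slices, res, res) float32
    transform_log: list[SliceTransform]
    subject_id: str = ""
    slice_index_map: list[int] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def resolution(self) -> int:
        return int(self.slices.shape[1])


def normalize_intensity(vol: VolumeImage) -> VolumeImage:
    """Min–max normalize a volume to [0, 1] (order-preserving, per volume).

    A constant-valued volume maps to all zeros with a warning.
    """
    data = vol.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        warnings.warn("constant-valued volume: normalized output is all zeros")
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return VolumeImage(data=out, affine=vol.affine.copy())


def _plane_axis(plane: str) -> int:
    try:
        return PLANE_AXES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}") from None


def extract_slices(
    vol: VolumeImage, plane: str, resolution: int = 256, subject_id: str = ""
) -> SliceStack:
    """Cut a canonicalized, normalized volume into per-plane 2D slices.

    Non-square slices are center-padded with zeros to square, then linearly
    resampled to ``resolution``; at native resolution the resize is the
    identity.  Intensities stay within [0, 1].
    """
    axis = _plane_axis(plane)
    moved = np.moveaxis(vol.data, axis, 0).astype(np.float32)
    n, h, w = moved.shape
    s = max(h, w)
    ph, pw = (s - h) // 2, (s - w) // 2
    padded = np.zeros((n, s, s), dtype=np.float32)
    padded[:, ph : ph + h, pw : pw + w] = moved
    scale = resolution / s
    if s == resolution:
        out = padded
    else:
        out = resize(
            padded,
            (n, resolution, resolution),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        ).astype(np.float32)
    log = [SliceTransform((h, w), (ph, pw), s, scale) for _ in range(n)]
    return SliceStack(
        plane=plane,
        slices=out,
        transform_log=log,
        subject_id=subject_id,
        slice_index_map=list(range(n)),
    )


def extract_mask_slices(
    mask: BinaryMask, plane: str, resolution: int = 256, subject_id: str = ""
) -> SliceStack:
    """Slice a binary mask; after any resize, values are re-binarized at 0.5."""
    as_vol = VolumeImage(data=mask.data.astype(np.float32), affine=mask.affine)
    stack = extract_slices(as_vol, plane, resolution=resolution, subject_id=subject_id)
    stack.slices = (stack.slices >= 0.5).astype(np.float32)
    return stack


def reassemble(
    pred_slices: np.ndarray,
    stack: SliceStack,
    geometry: VolumeImage | BinaryMask,
    threshold: float = 0.5,
) -> BinaryMask:
    """Invert the slice transform and stack per-slice predictions into 3D.

    ``pred_slices`` may be probabilities or binary values, one 2D grid per
    slice in ``stack``; they are inverse-resized, inverse-padded, stacked
    along the slicing axis and thresholded at ``threshold`` (inclusive).
    """
    pred_slices = np.asarray(pred_slices, dtype=np.float32)
    if pred_slices.shape[0] != stack.n_slices:
        raise ConsistencyError(
            f"{pred_slices.shape[0]} prediction slices for a stack of {stack.n_slices}"
        )
    axis = _plane_axis(stack.plane)
    tf = stack.transform_log[0]
    h, w = tf.orig_shape
    ph, pw = tf.pad_before
    s = tf.square
    if s == pred_slices.shape[1]:
        squares = pred_slices
    else:
        squares = resize(
            pred_slices,
            (stack.n_slices, s, s),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        ).astype(np.float32)
    cropped = squares[:, ph : ph + h, pw : pw + w]
    volume = np.moveaxis(cropped, 0, axis)
    if volume.shape != geometry.data.shape:
        raise ConsistencyError(
            f"reassembled shape {volume.shape} != geometry {geometry.data.shape}"
        )
    binary = (volume >= threshold).astype(np.uint8)
    return BinaryMask(data=binary, affine=np.asarray(geometry.affine).copy())


def export_png(stack: SliceStack, out_dir) -> list:
    """Optional inspection export: write each slice as an 8-bit grayscale PNG.

    Intensities in [0, 1] map to 0–255.  The canonical data path stays
    in-memory; this is for eyeballing training slices only.
    """
    import imageio.v3 as iio
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = stack.subject_id or "stack"
    paths = []
    for i in range(stack.n_slices):
        img = np.clip(stack.slices[i], 0.0, 1.0)
        path = out_dir / f"{prefix}_{stack.plane}_{i:03d}.png"
        iio.imwrite(path, (img * 255).round().astype(np.uint8))
        paths.append(path)
    return paths
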