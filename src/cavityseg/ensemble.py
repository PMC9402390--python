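"""Multi-view fusion and post-processing.

The three per-plane predictions are reassembled into 3D binary masks and
fused per voxel by majority vote (a voxel is kept iff at least ``min_votes``
of the 3 plane models labeled it, default 2).  The fused mask is then cleaned
by connected-component filtering and screened with a minimum-volume detection
threshold: small spurious segmentations (default < 0.5 ml, i.e. 500 voxels at
1 mm isotropic) are discarded and reported as "no resection detected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError
from .metrics import mask_volume_ml
from .preprocess import PLANES, extract_slices, normalize_intensity, reassemble
from .segmenter import PlaneModel, predict_slices
from .volume_io import BinaryMask, VolumeImage, canonicalize, require_same_geometry

__all__ = [
    "EnsembleConfig",
    "majority_vote",
    "filter_components",
    "screen_detection",
    "segment_volume",
]


@dataclass
class EnsembleConfig:
    min_votes: int = 2
    component_mode: str = "largest"  # "largest" | "min_size"
    min_component_voxels: int = 50
    detection_threshold_ml: float = 0.5
    connectivity: int = 26  # 6 or 26

    def __post_init__(self) -> None:
        if not 1 <= self.min_votes <= 3:
            raise ValueError("min_votes must be in {1, 2, 3}")
        if self.component_mode not in ("largest", "min_size"):
            raise ValueError(f"unknown component_mode {self.component_mode!r}")
        if self.min_component_voxels < 0 or self.detection_threshold_ml < 0:
            raise ValueError("thresholds must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def majority_vote(
    mask_ax: BinaryMask, mask_cor: BinaryMask, mask_sag: BinaryMask,
    min_votes: int = 2,
) -> BinaryMask:
    """Per-voxel vote fusion: keep a voxel iff >= ``min_votes`` masks set it."""
    require_same_geometry(mask_ax, mask_cor, "vote inputs")
    require_same_geometry(mask_ax, mask_sag, "vote inputs")
    if not 1 <= min_votes <= 3:
        raise ValueError("min_votes must be in {1, 2, 3}")
    votes = (
        mask_ax.data.astype(np.uint8)
        + mask_cor.data.astype(np.uint8)
        + mask_sag.data.astype(np.uint8)
    )
    return BinaryMask(data=(votes >= min_votes).astype(np.uint8),
                      affine=mask_ax.affine.copy())


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def filter_components(mask: BinaryMask, config: EnsembleConfig | None = None) -> BinaryMask:
    """Remove isolated voxels/components; never adds voxels.

    ``largest`` keeps exactly the single largest connected component of a
    non-empty mask; ``min_size`` keeps every component with at least
    ``min_component_voxels`` voxels.  Empty input passes through empty.
    """
    config = config or EnsembleConfig()
    labeled, n = ndimage.label(mask.data, structure=_structure(config.connectivity))
    if n == 0:
        return BinaryMask(data=np.zeros_like(mask.data), affine=mask.affine.copy())
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    if config.component_mode == "largest":
        keep = labeled == int(np.argmax(counts))
    else:
        good = np.flatnonzero(counts >= config.min_component_voxels)
        keep = np.isin(labeled, good)
    return BinaryMask(data=keep.astype(np.uint8), affine=mask.affine.copy())


def screen_detection(
    mask: BinaryMask, config: EnsembleConfig | None = None
) -> tuple[bool, BinaryMask]:
    """Volume-based detection screen on a post-filter mask.

    Detected iff the total mask volume reaches ``detection_threshold_ml``;
    otherwise the returned mask is emptied.
    """
    config = config or EnsembleConfig()
    detected = mask_volume_ml(mask) >= config.detection_threshold_ml
    if not detected:
        mask = BinaryMask(data=np.zeros_like(mask.data), affine=mask.affine.copy())
    return detected, mask


def segment_volume(
    models: dict[str, PlaneModel],
    vol: VolumeImage,
    config: EnsembleConfig | None = None,
) -> tuple[BinaryMask, bool]:
    """Full inference pipeline for one volume.

    Order: canonicalize → normalize → per-plane slice extraction → prediction
    → 3D reassembly → majority vote → connected-component filtering →
    detection screening.  The returned mask shares the input geometry.
    """
    config = config or EnsembleConfig()
    missing = set(PLANES) - set(models)
    if missing:
        raise ConsistencyError(f"missing plane models: {sorted(missing)}")
    can = canonicalize(vol)
    norm = normalize_intensity(can)
    plane_masks = {}
    for plane in PLANES:
        model = models[plane]
        stack = extract_slices(norm, plane, resolution=model.config.resolution)
        proba = predict_slices(model, stack)
        plane_masks[plane] = reassemble(
            proba, stack, can, threshold=model.config.binarization_threshold
        )
    fused = majority_vote(
        plane_masks["axial"], plane_masks["coronal"], plane_masks["sagittal"],
        min_votes=config.min_votes,
    )
    cleaned = filter_components(fused, config)
    detected, screened = screen_detection(cleaned, config)
    return screened, detected
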