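"""Periosteal / cortical / trabecular segmentation of density volumes.

Bone is separated from soft tissue by the standard fixed global threshold
of 400 mg HA/cm^3 (inclusive).  The periosteal surface is found
automatically slice-by-slice (morphological closing, hole filling,
largest component); the cortical and trabecular compartments are then
split by a dilation/erosion (dual-threshold style) procedure that closes
intracortical pores and grows the medullary region back over the
trabecular struts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volume import CORT, TRAB, VOID, DensityVolume, LabelVolume

log = logging.getLogger(__name__)

# 8-neighbourhood in-slice, 26-neighbourhood in 3-D.
_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationConfig:
    bone_threshold: float = 400.0      # mg HA/cm^3, inclusive
    closing_radius: int = 3            # voxels, periosteal contour closing
    dilation_erosion_radius: int = 2   # voxels, cortical pore closing
    opening_radius: int = 1            # voxels, strips strut-scale structures
    min_island_voxels: int = 27        # 3-D islands smaller than this dropped

    def validate(self) -> None:
        if not self.bone_threshold > 0:
            raise ValueError("bone_threshold must be positive")
        if self.closing_radius < 1 or self.dilation_erosion_radius < 1:
            raise ValueError("morphological radii must be >= 1")


def bone_mask(vol: DensityVolume, cfg: SegmentationConfig | None = None,
              ) -> np.ndarray:
    """Binary bone mask: density >= threshold (inclusive)."""
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    return vol.data >= cfg.bone_threshold


def _largest_component_2d(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT_2D)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def periosteal_mask(vol: DensityVolume, cfg: SegmentationConfig | None = None,
                    bone: np.ndarray | None = None) -> np.ndarray:
    """Automatic periosteal contour, slice by slice.

    Per slice: close the bone mask, fill enclosed holes, keep the largest
    connected component.  The result always contains the bone mask of that
    component; slices with no bone yield an empty contour (logged).
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    if bone is None:
        bone = bone_mask(vol, cfg)
    selem = disk(cfg.closing_radius)
    out = np.zeros_like(bone)
    for k in range(bone.shape[2]):
        sl = bone[:, :, k]
        if not sl.any():
            log.warning("slice %d contains no bone; empty periosteal contour", k)
            continue
        closed = ndimage.binary_closing(sl, structure=selem)
        filled = ndimage.binary_fill_holes(closed)
        out[:, :, k] = _largest_component_2d(filled)
    return out


def dual_threshold(vol: DensityVolume, periosteal: np.ndarray,
                   cfg: SegmentationConfig | None = None,
                   bone: np.ndarray | None = None) -> LabelVolume:
    """Split bone inside the periosteal contour into cortical and
    trabecular compartments.

    Per slice: a closing (``dilation_erosion_radius``) seals intracortical
    pores; an opening (``opening_radius``) then strips strut-scale
    structures so that only compact cortical bone remains, and the
    components of that residue connected to the periosteal surface form
    the cortical compartment.  Everything inside the resulting
    endocortical contour is the trabecular region.  Bone islands below
    ``min_island_voxels`` (26-connectivity) are relabelled void.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    if bone is None:
        bone = bone_mask(vol, cfg)
    bone = bone & periosteal
    selem_close = disk(cfg.dilation_erosion_radius)
    selem_open = disk(cfg.opening_radius)

    labels = np.zeros(bone.shape, dtype=np.uint8)
    discontinuous = 0
    n_slices = bone.shape[2]
    for k in range(n_slices):
        sl, peri = bone[:, :, k], periosteal[:, :, k]
        if not sl.any():
            continue
        ring = peri & ~ndimage.binary_erosion(peri, structure=_STRUCT_2D)
        compact = ndimage.binary_opening(sl, structure=selem_open)
        comp, n = ndimage.label(compact, structure=_STRUCT_2D)
        touching = np.unique(comp[ring & compact])
        touching = touching[touching != 0]
        cortex = np.isin(comp, touching) if touching.size else compact
        # Close intracortical pores: the closing may only annex void voxels,
        # never bone, so trabecular struts abutting the shell stay trabecular.
        pores = ndimage.binary_closing(cortex, structure=selem_close) & ~sl
        cortex = (cortex | pores) & peri
        if (peri & ~cortex & ring).any():
            discontinuous += 1
        endo = peri & ~cortex
        labels[:, :, k][sl] = CORT
        labels[:, :, k][sl & endo] = TRAB
    if discontinuous > n_slices / 2:
        raise ValueError(
            f"cortex unresolvable: shell discontinuous on {discontinuous}"
            f"/{n_slices} slices")

    # Remove small 3-D bone islands.
    if cfg.min_island_voxels > 1:
        comp, n = ndimage.label(labels != VOID, structure=_STRUCT_3D)
        if n:
            counts = np.bincount(comp.ravel())
            small = np.flatnonzero(counts < cfg.min_island_voxels)
            small = small[small != 0]
            if small.size:
                labels[np.isin(comp, small)] = VOID
    return LabelVolume(labels=labels, voxel_size=vol.voxel_size,
                       provenance="dual_threshold", site=vol.site,
                       scan_id=vol.scan_id)


def mean_cross_sectional_area(periosteal: np.ndarray, voxel_size: float) -> float:
    """Mean periosteal cross-sectional area over slices, in mm^2."""
    per_slice = periosteal.sum(axis=(0, 1))
    return float(per_slice.mean() * voxel_size ** 2)


def segment(vol: DensityVolume, cfg: SegmentationConfig | None = None,
            ) -> tuple[np.ndarray, np.ndarray, LabelVolume]:
    """Full segmentation: returns (bone, periosteal, labels)."""
    cfg = cfg or SegmentationConfig()
    bone = bone_mask(vol, cfg)
    peri = periosteal_mask(vol, cfg, bone=bone)
    labels = dual_threshold(vol, peri, cfg, bone=bone)
    return bone, peri, labels
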