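"""Slice standardization, classical binary masks, and registration channels.

The pipeline standardizes every slice to a common geometry (500 mm field of
view on a 512² grid by default), truncates intensities above 1024 HU, and
flags probable metal implants (>= 50 voxels above 2000 HU, counted before
truncation).  Binary masks are produced with the classical recipe: HU
thresholding followed by connected-component selection and morphology.
Organ masks that in production come from learned segmentation models
(liver, spleen, abdominal muscle) are accepted as external inputs or taken
from phantom ground truth.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from . import config as cfg
from .types import (
    CTSlice,
    MaskSet,
    MultiChannelImage,
    TissueClass,
    TissueClassMap,
)

log = logging.getLogger(__name__)

# masks required as registration channels, per slice type (after the CT)
REQUIRED_CHANNELS = {
    "liver": ["liver", "spleen", "body", "vertebra"],
    "abdomen": ["body", "vertebra", "muscle", "isat"],
    "thigh": ["body", "bone", "lean"],
}


def standardize(
    ct: CTSlice,
    target_fov_mm: float = cfg.TARGET_FOV_MM,
    target_grid: int = cfg.TARGET_GRID,
) -> CTSlice:
    """Resample to the common geometry, truncate HU, set the metal flag.

    The metal flag is decided on the *pre-truncation* values (truncation
    would destroy the >2000 HU evidence); flagged slices are marked, never
    excluded.  The operation is idempotent.
    """
    pixels = np.asarray(ct.pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("slice contains non-finite pixel values")
    if any(s <= 0 for s in ct.spacing_mm):
        raise ValueError(f"non-positive spacing {ct.spacing_mm}")

    metal = int(np.count_nonzero(pixels > cfg.METAL_HU)) >= cfg.METAL_VOXEL_COUNT

    target_spacing = target_fov_mm / target_grid
    same_grid = ct.shape == (target_grid, target_grid) and np.allclose(
        ct.spacing_mm, (target_spacing, target_spacing), rtol=1e-9, atol=1e-9
    )
    if same_grid:
        out_pixels = pixels
    else:
        # align physical centres of the two grids, sample with linear interp
        src_center = ((ct.shape[0] - 1) * ct.spacing_mm[0] / 2.0,
                      (ct.shape[1] - 1) * ct.spacing_mm[1] / 2.0)
        tgt_center = ((target_grid - 1) * target_spacing / 2.0,) * 2
        rows = (np.arange(target_grid) * target_spacing - tgt_center[0] + src_center[0])
        cols = (np.arange(target_grid) * target_spacing - tgt_center[1] + src_center[1])
        rr = rows / ct.spacing_mm[0]
        cc = cols / ct.spacing_mm[1]
        coords = np.meshgrid(rr, cc, indexing="ij")
        out_pixels = ndi.map_coordinates(
            pixels, coords, order=1, mode="constant", cval=cfg.HU_FLOOR
        )

    out_pixels = np.minimum(out_pixels, cfg.HU_TRUNCATE)
    flags = set(ct.flags)
    if metal:
        flags.add("metal_suspect")
    return CTSlice(
        pixels=out_pixels,
        spacing_mm=(target_spacing, target_spacing),
        slice_type=ct.slice_type,
        subject_id=ct.subject_id,
        sex=ct.sex,
        flags=flags,
    )


def _keep_largest(mask: np.ndarray, k: int) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][: min(k, n)] + 1
    return np.isin(labels, keep)


def body_mask(ct: CTSlice, closing_radius: int = cfg.BODY_CLOSING_RADIUS) -> np.ndarray:
    """Body outline: threshold > -190 HU, largest object(s), close, fill.

    For the thigh station the two largest objects (left and right thigh)
    are kept; elsewhere only the largest, which eliminates the CT table and
    other non-body objects.
    """
    thr = ct.pixels > cfg.BODY_THRESHOLD_HU
    if not thr.any():
        raise ValueError("no body found: threshold result is empty")
    k = 2 if ct.slice_type == "thigh" else 1
    mask = _keep_largest(thr, k)
    mask = morphology.closing(mask, morphology.disk(closing_radius))
    return ndi.binary_fill_holes(mask)


def vertebra_mask(ct: CTSlice, opening_radius: int = cfg.VERTEBRA_OPENING_RADIUS) -> np.ndarray:
    """Vertebra: voxels above 200 HU, opened to remove speckle."""
    if ct.slice_type not in ("liver", "abdomen"):
        raise ValueError(f"vertebra mask undefined for slice_type {ct.slice_type!r}")
    thr = ct.pixels > cfg.VERTEBRA_THRESHOLD_HU
    return morphology.opening(thr, morphology.disk(opening_radius))


def thigh_bone_and_lean_masks(ct: CTSlice) -> tuple[np.ndarray, np.ndarray]:
    """Cortical bone (marrow filled solid) and lean-tissue masks for the thigh.

    Bone: > 200 HU with the enclosed marrow region filled, so each thigh
    contributes one solid disk (fewer local minima during registration).
    Lean: HU in [-29, 150], with the filled bone region excluded.
    """
    if ct.slice_type != "thigh":
        raise ValueError("bone/lean masks are defined for the thigh slice only")
    bone_thr = ct.pixels > cfg.BONE_THRESHOLD_HU
    if not bone_thr.any():
        warnings.warn("no bone voxels found on thigh slice; returning empty masks")
        empty = np.zeros(ct.shape, dtype=bool)
        return empty, empty
    bone = ndi.binary_fill_holes(bone_thr)
    lo, hi = cfg.LEAN_WINDOW_HU
    lean = (ct.pixels >= lo) & (ct.pixels <= hi) & ~bone
    return bone, lean


def isat_mask(
    ct: CTSlice,
    muscle_mask: np.ndarray,
    body: np.ndarray,
    closing_radius: int = cfg.ISAT_CLOSING_RADIUS,
) -> np.ndarray:
    """Region enclosed by the (closed) abdominal muscle wall, wall excluded.

    The muscle wall is morphologically closed with a large element so that
    anatomically plausible gaps (e.g. vague anterior muscles) do not leak
    the interior, then the interior is extracted by hole filling.
    """
    if ct.slice_type != "abdomen":
        raise ValueError("ISAT mask is defined for the abdominal slice only")
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    if not muscle_mask.any():
        raise ValueError("empty muscle mask")
    closed = morphology.closing(muscle_mask, morphology.disk(closing_radius))
    filled = ndi.binary_fill_holes(closed)
    return filled & ~closed & np.asarray(body, dtype=bool)


def tissue_class_map(ct: CTSlice, body: np.ndarray) -> TissueClassMap:
    """Exhaustive air/adipose/soft/bone labeling for the regularization map.

    Outside the body everything is air regardless of HU; inside, the class
    boundaries reuse the mask windows (-190, -30, 150 HU).  Every voxel
    receives exactly one label.
    """
    hu = ct.pixels
    body = np.asarray(body, dtype=bool)
    b = cfg.CLASS_BOUNDS_HU
    labels = np.full(ct.shape, int(TissueClass.AIR), dtype=np.int8)
    inside = body & (hu >= b["air_adipose"])
    labels[inside & (hu < b["adipose_soft"])] = int(TissueClass.ADIPOSE)
    labels[inside & (hu >= b["adipose_soft"]) & (hu <= b["soft_bone"])] = int(
        TissueClass.SOFT_TISSUE
    )
    labels[inside & (hu > b["soft_bone"])] = int(TissueClass.BONE)
    return TissueClassMap(labels, dict(cfg.REGULARIZATION_WEIGHTS))


def normalize_ct(pixels: np.ndarray) -> np.ndarray:
    """Affine map of HU from [-1024, 1024] to [0, 1], clipped."""
    lo, hi = cfg.CT_NORM_RANGE_HU
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)


def assemble_channels(
    ct: CTSlice,
    masks: MaskSet,
    channel_weights: dict | None = None,
) -> MultiChannelImage:
    """Stack the CT channel (normalized to [0, 1]) with its guidance masks.

    Channel order and default weights follow the per-station configuration:
    the CT image carries the highest weight, the masks contribute the
    high-level features.  A missing required mask raises, naming it.
    """
    weights = dict(cfg.CHANNEL_WEIGHTS[ct.slice_type])
    if channel_weights:
        weights.update(channel_weights)
    required = REQUIRED_CHANNELS[ct.slice_type]
    for name in required:
        if name not in masks:
            raise ValueError(f"missing mask: {name}")
        if masks[name].shape != ct.shape:
            raise ValueError(f"mask {name!r} not aligned to slice grid")

    channels = [normalize_ct(ct.pixels)]
    names = ["ct"]
    w = [weights["ct"]]
    for name in required:
        channels.append(masks[name].astype(float))
        names.append(name)
        w.append(weights[name])
    return MultiChannelImage(
        channels=np.stack(channels),
        channel_names=names,
        channel_weights=np.asarray(w),
        spacing_mm=ct.spacing_mm,
        slice_type=ct.slice_type,
        subject_id=ct.subject_id,
        backgrounds=np.zeros(len(names)),  # normalized air = 0, masks = 0
    )


def preprocess_subject(
    ct: CTSlice,
    external_masks: dict[str, np.ndarray] | None = None,
    target_fov_mm: float = cfg.TARGET_FOV_MM,
    target_grid: int = cfg.TARGET_GRID,
) -> tuple[CTSlice, MaskSet, TissueClassMap]:
    """Standardize one slice and derive every mask its station needs.

    ``external_masks`` supplies the segmentation-model organs (liver,
    spleen, abdominal muscle) on the *standardized* grid — in phantom runs
    these are the ground-truth masks.
    """
    std = standardize(ct, target_fov_mm, target_grid)
    ext = external_masks or {}
    masks: dict[str, np.ndarray] = {}
    prov: dict[str, str] = {}
    body = body_mask(std)
    masks["body"] = body
    prov["body"] = "threshold_morphology"

    if std.slice_type in ("liver", "abdomen"):
        masks["vertebra"] = vertebra_mask(std)
        prov["vertebra"] = "threshold_morphology"
    if std.slice_type == "liver":
        for name in ("liver", "spleen"):
            if name not in ext:
                raise ValueError(f"missing mask: {name} (external segmentation required)")
            masks[name] = np.asarray(ext[name], dtype=bool)
            prov[name] = "external"
        if not masks["spleen"].any():
            log.info("subject %s: spleen mask empty (out of protocol) — excluded",
                     std.subject_id)
            raise SpleenNotVisible(std.subject_id)
    if std.slice_type == "abdomen":
        if "muscle" not in ext:
            raise ValueError("missing mask: muscle (external segmentation required)")
        masks["muscle"] = np.asarray(ext["muscle"], dtype=bool)
        prov["muscle"] = "external"
        masks["isat"] = isat_mask(std, masks["muscle"], body)
        prov["isat"] = "threshold_morphology"
    if std.slice_type == "thigh":
        bone, lean = thigh_bone_and_lean_masks(std)
        masks["bone"], masks["lean"] = bone, lean
        prov["bone"] = prov["lean"] = "threshold_morphology"

    classmap = tissue_class_map(std, body)
    return std, MaskSet(masks, prov), classmap


class SpleenNotVisible(ValueError):
    """Raised for liver slices whose spleen mask is empty (out of protocol)."""
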