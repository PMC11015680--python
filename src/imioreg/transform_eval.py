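"""Transform quality metrics: Jacobians, folds, inverse consistency, group maps.

Inverse consistency (IC) is measured by composing the forward and reverse
registrations of a pair: for images x and y with transforms T_xy (x's grid
into y) and T_yx, the composite T_yx o T_xy should be the identity.  The
vector magnitude error (VME, mm) is the mean displacement magnitude of the
composite over a body region Omega; the intensity magnitude error (IME,
HU) is the mean absolute difference between the image and itself resampled
through the composite.  Both composite orders are computed and the pair
metric is their average.

Diffeomorphic quality is summarized by the Jacobian determinant of the
transform (central differences in the interior, one-sided at borders):
det = 1 means no local area change, det < 0 a fold.  The natural log of
the determinant is the symmetric expansion/contraction measure used for
group statistics and voxel-wise regression.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .register import compose
from .types import CTSlice, DisplacementField, EvalReport, JacobianMap


def jacobian_determinant(field: DisplacementField) -> JacobianMap:
    """Determinant of (I + dv/dp), derivatives in mm over mm."""
    v = field.vectors
    sy, sx = field.spacing_mm
    dvy_dy, dvy_dx = np.gradient(v[..., 0], sy, sx)
    dvx_dy, dvx_dx = np.gradient(v[..., 1], sy, sx)
    det = (1.0 + dvy_dy) * (1.0 + dvx_dx) - dvy_dx * dvx_dy
    with np.errstate(invalid="ignore", divide="ignore"):
        log_det = np.where(det > 0, np.log(np.where(det > 0, det, 1.0)), np.nan)
    return JacobianMap(det=det, log_det=log_det)


def count_folds(jac: JacobianMap, region: np.ndarray | None = None) -> int:
    """Voxels with strictly negative determinant (det = 0 is not a fold)."""
    neg = jac.det < 0
    if region is not None:
        if region.shape != jac.det.shape:
            raise ValueError("region grid mismatch")
        neg = neg & np.asarray(region, dtype=bool)
    return int(np.count_nonzero(neg))


def count_degenerate(jac: JacobianMap, region: np.ndarray | None = None) -> int:
    """Voxels with exactly zero determinant, reported separately from folds."""
    zero = jac.det == 0
    if region is not None:
        zero = zero & np.asarray(region, dtype=bool)
    return int(np.count_nonzero(zero))


def _sample_image_at(ct: CTSlice, points_mm_y, points_mm_x) -> np.ndarray:
    """Linear interpolation of a slice at physical (mm) points."""
    ry = points_mm_y / ct.spacing_mm[0]
    rx = points_mm_x / ct.spacing_mm[1]
    return ndi.map_coordinates(
        np.asarray(ct.pixels, dtype=float), [ry, rx], order=1, mode="nearest"
    )


def inverse_consistency(
    field_xy: DisplacementField,
    field_yx: DisplacementField,
    image_x: CTSlice,
    omega: np.ndarray,
    runtime_s: float = float("nan"),
) -> EvalReport:
    """VME and IME of the composite T_yx o T_xy over the body region of x.

    ``omega`` lives on the field grid.  ``image_x`` may be at any
    resolution: intensities are sampled at physical coordinates.  Fold
    counting for the report uses the forward field within omega.
    """
    omega = np.asarray(omega, dtype=bool)
    if omega.shape != field_xy.grid_shape:
        raise ValueError("omega grid does not match field grid")
    if not omega.any():
        raise ValueError("empty omega region")

    comp = compose(field_yx, field_xy)
    vme_map = comp.magnitude()
    vme = float(vme_map[omega].mean())

    h, w = comp.grid_shape
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    py = gy * comp.spacing_mm[0] + comp.vectors[..., 0]
    px = gx * comp.spacing_mm[1] + comp.vectors[..., 1]
    i_comp = _sample_image_at(image_x, py, px)
    i_here = _sample_image_at(
        image_x, gy * comp.spacing_mm[0], gx * comp.spacing_mm[1]
    )
    ime = float(np.abs(i_here - i_comp)[omega].mean())

    folds = count_folds(jacobian_determinant(field_xy), omega)
    return EvalReport(
        vme_mm=vme, ime_hu=ime, n_folds=folds,
        omega_size=int(omega.sum()), runtime_s=runtime_s,
    )


def pair_consistency(
    field_xy: DisplacementField,
    field_yx: DisplacementField,
    image_x: CTSlice,
    image_y: CTSlice,
    omega_x: np.ndarray,
    omega_y: np.ndarray,
    runtime_s: float = float("nan"),
) -> EvalReport:
    """Both composite orders averaged into a single value per pair."""
    r_xy = inverse_consistency(field_xy, field_yx, image_x, omega_x)
    r_yx = inverse_consistency(field_yx, field_xy, image_y, omega_y)
    return EvalReport(
        vme_mm=0.5 * (r_xy.vme_mm + r_yx.vme_mm),
        ime_hu=0.5 * (r_xy.ime_hu + r_yx.ime_hu),
        n_folds=0.5 * (r_xy.n_folds + r_yx.n_folds),
        omega_size=int(omega_x.sum() + omega_y.sum()),
        runtime_s=runtime_s,
    )


def vme_map(field_xy: DisplacementField, field_yx: DisplacementField) -> np.ndarray:
    """Per-voxel composite displacement magnitude (mm) on x's grid."""
    return compose(field_yx, field_xy).magnitude()


def group_statistics(
    registered_hu: np.ndarray | None = None,
    vme_maps: np.ndarray | None = None,
    log_jacs: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Voxel-wise cohort mean/STD images from aligned per-subject stacks.

    STD is the population standard deviation (divide by n).  Any subset of
    the three stacks may be given; each must have n >= 2 subjects for its
    STD output.
    """
    out: dict[str, np.ndarray] = {}
    for name, stack, with_std in (
        ("hu", registered_hu, True),
        ("vme", vme_maps, False),
        ("logjac", log_jacs, True),
    ):
        if stack is None:
            continue
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3:
            raise ValueError(f"{name} stack must be (n, H, W)")
        out[f"mean_{name}"] = np.nanmean(stack, axis=0)
        if with_std:
            if stack.shape[0] < 2:
                raise ValueError(f"need n >= 2 subjects for std_{name}")
            out[f"std_{name}"] = np.nanstd(stack, axis=0)  # population STD
    return out
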