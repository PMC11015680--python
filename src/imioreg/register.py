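"""Multi-channel deformable registration by discrete block-move optimization.

The transform model is a dense displacement field (the least restricted
model).  The objective is a weighted multi-channel sum of squared
differences plus a tissue-weighted first-difference regularizer,

    E(v) = sum_c w_c sum_i (F_c(i) - M_c(i + v(i)/h))^2
           + s * sum_{(i,j) in N4} lam(i,j) ||v(i) - v(j)||^2,

with lam(i, j) the mean of the elasticity-class weights at i and j (low for
air/fat/soft tissue, higher for bone).  Optimization is coarse-to-fine on a
Gaussian pyramid; at each level the field is refined by iterated discrete
moves: square blocks of voxels receive one candidate update
(+-step_size voxels along each axis, additive rule) and a move is accepted
only if it strictly lowers the total energy.  Blocks are visited in a
checkerboard order so simultaneously updated blocks share no regularizer
edge, which makes the per-iteration energy decrease exact — the total
energy is non-increasing across outer iterations at every level, by
construction.  After local convergence the step is halved a configured
number of times for sub-voxel refinement.

The multi-resolution schedule starts at the coarsest level and stops at
level one: the returned field (and any image registered with it) lives on
the original grid downscaled by a factor of two in each dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi

from .types import (
    DisplacementField,
    MultiChannelImage,
    RegistrationParams,
    TissueClassMap,
)

_ENERGY_SLACK = 1e-8  # float tolerance on the monotonicity contract


def warp_image(
    image: np.ndarray,
    field: DisplacementField,
    interpolation: str = "linear",
    background: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` through the field: out(i) = image(i + v(i)/h)."""
    if interpolation == "linear":
        order = 1
    elif interpolation == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if image.shape != field.grid_shape:
        raise ValueError("field grid does not match image grid")
    h, w = image.shape
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [
        gy + field.vectors[..., 0] / field.spacing_mm[0],
        gx + field.vectors[..., 1] / field.spacing_mm[1],
    ]
    return ndi.map_coordinates(
        np.asarray(image, dtype=float), coords, order=order, mode="constant",
        cval=background,
    )


def resample_via_field(
    image: np.ndarray,
    image_spacing,
    field: DisplacementField,
    interpolation: str = "linear",
    background: float = 0.0,
) -> np.ndarray:
    """Warp an image that lives on its own grid onto the field's grid.

    The field gives target physical points p + v(p) (mm); the image is
    sampled there using its own spacing, so e.g. a full-resolution moving
    slice can be registered onto the half-resolution output grid.
    """
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    h, w = field.grid_shape
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    py = (gy * field.spacing_mm[0] + field.vectors[..., 0]) / image_spacing[0]
    px = (gx * field.spacing_mm[1] + field.vectors[..., 1]) / image_spacing[1]
    return ndi.map_coordinates(
        np.asarray(image, dtype=float), [py, px], order=order, mode="constant",
        cval=background,
    )


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Composite transform (outer o inner): v(p) = v_in(p) + v_out(p + v_in(p)).

    ``outer`` is sampled with linear interpolation at the inner-displaced
    points; beyond the grid its edge values are used.
    """
    if not np.allclose(outer.spacing_mm, inner.spacing_mm):
        raise ValueError("spacing mismatch between fields")
    h, w = inner.grid_shape
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    py = gy + inner.vectors[..., 0] / inner.spacing_mm[0]
    px = gx + inner.vectors[..., 1] / inner.spacing_mm[1]
    out = np.empty_like(inner.vectors)
    for k in range(2):
        out[..., k] = inner.vectors[..., k] + ndi.map_coordinates(
            outer.vectors[..., k], [py, px], order=1, mode="nearest"
        )
    return DisplacementField(out, inner.spacing_mm)


def _ssd_map(
    fixed: np.ndarray,      # (C, H, W)
    moving: np.ndarray,     # (C, H, W)
    weights: np.ndarray,    # (C,)
    backgrounds: np.ndarray,
    vectors: np.ndarray,    # (H, W, 2) mm
    spacing,
) -> np.ndarray:
    h, w = fixed.shape[1:]
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [gy + vectors[..., 0] / spacing[0], gx + vectors[..., 1] / spacing[1]]
    out = np.zeros((h, w))
    for c in range(fixed.shape[0]):
        if weights[c] == 0:
            continue
        warped = ndi.map_coordinates(
            moving[c], coords, order=1, mode="constant", cval=backgrounds[c]
        )
        out += weights[c] * (fixed[c] - warped) ** 2
    return out


def multichannel_ssd(
    fixed: MultiChannelImage,
    moving: MultiChannelImage,
    field: DisplacementField,
    region: np.ndarray | None = None,
) -> float:
    """Weighted multi-channel SSD of ``moving`` warped by ``field`` vs ``fixed``."""
    if fixed.channel_names != moving.channel_names or not np.allclose(
        fixed.channel_weights, moving.channel_weights
    ):
        raise ValueError("fixed and moving must share channel lists and weights")
    smap = _ssd_map(
        fixed.channels, moving.channels, fixed.channel_weights,
        moving.backgrounds, field.vectors, fixed.spacing_mm,
    )
    if region is not None:
        if region.shape != smap.shape:
            raise ValueError("region grid mismatch")
        smap = smap * np.asarray(region, dtype=bool)
    return float(smap.sum())


def _reg_energy(vectors: np.ndarray, lam: np.ndarray) -> float:
    dv = vectors[1:] - vectors[:-1]
    lv = 0.5 * (lam[1:] + lam[:-1])
    dh = vectors[:, 1:] - vectors[:, :-1]
    lh = 0.5 * (lam[:, 1:] + lam[:, :-1])
    return float((lv * (dv**2).sum(-1)).sum() + (lh * (dh**2).sum(-1)).sum())


def regularization_energy(field: DisplacementField, classmap: TissueClassMap) -> float:
    """Tissue-weighted first-difference penalty over the 4-neighborhood."""
    lam = classmap.weight_image()
    if lam.shape != field.grid_shape:
        raise ValueError("class map grid does not match field grid")
    return _reg_energy(field.vectors, lam)


@dataclass
class RegistrationResult:
    """Field plus optimizer diagnostics (per-level energy traces)."""

    field: DisplacementField
    energy_traces: dict[int, list[float]] = dc_field(default_factory=dict)
    converged: bool = True
    warnings: list[str] = dc_field(default_factory=list)


def _downsample2(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    return ndi.gaussian_filter(image, sigma)[::2, ::2]


def downsample(image: np.ndarray, n_levels: int, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-smooth and decimate by two, ``n_levels`` times."""
    out = np.asarray(image, dtype=float)
    for _ in range(n_levels):
        out = _downsample2(out, sigma)
    return out


def downsample_mask(mask: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.asarray(mask, dtype=bool)
    for _ in range(n_levels):
        out = out[::2, ::2]
    return out


def _optimize_level(fixed, moving, weights, backgrounds, lam, spacing, vectors, params):
    """Block-move descent at one pyramid level.  Returns (vectors, trace, converged)."""
    H, W = fixed.shape[1:]
    b = int(min(params.block_size, H, W))
    rows = np.arange(H)[:, None] // b
    cols = np.arange(W)[None, :] // b
    nbx = (W + b - 1) // b
    nby = (H + b - 1) // b
    bid = np.broadcast_to(rows * nbx + cols, (H, W)).astype(np.int64)
    nblocks = nby * nbx
    block_color = (np.add.outer(np.arange(nby), np.arange(nbx)) % 2).ravel()

    # boundary edge bookkeeping (vertical = between rows i, i+1)
    vb = np.arange(b - 1, H - 1, b)
    hb = np.arange(b - 1, W - 1, b)
    bid_v_above = bid[vb, :].ravel()
    bid_v_below = bid[vb + 1, :].ravel()
    bid_h_left = bid[:, hb].ravel()
    bid_h_right = bid[:, hb + 1].ravel()

    def energy(vecs):
        s = _ssd_map(fixed, moving, weights, backgrounds, vecs, spacing).sum()
        return float(s + params.reg_scale * _reg_energy(vecs, lam))

    step_vox = params.step_size
    halvings = 0
    trace = [energy(vectors)]
    converged = False
    it = 0
    while it < params.max_iterations_per_level:
        changed_any = False
        for col in (0, 1):
            s0 = _ssd_map(fixed, moving, weights, backgrounds, vectors, spacing)
            cand = [
                np.array([step_vox * spacing[0], 0.0]),
                np.array([-step_vox * spacing[0], 0.0]),
                np.array([0.0, step_vox * spacing[1]]),
                np.array([0.0, -step_vox * spacing[1]]),
            ]
            d_v = vectors[vb + 1, :, :] - vectors[vb, :, :]
            lam_v = (0.5 * (lam[vb + 1, :] + lam[vb, :])).ravel()
            d_h = vectors[:, hb + 1, :] - vectors[:, hb, :]
            lam_h = (0.5 * (lam[:, hb + 1] + lam[:, hb])).ravel()

            deltas = np.zeros((len(cand), nblocks))
            for ci, u in enumerate(cand):
                du_map = _ssd_map(
                    fixed, moving, weights, backgrounds, vectors + u, spacing
                ) - s0
                deltas[ci] = np.bincount(bid.ravel(), du_map.ravel(), minlength=nblocks)
                u2 = float(u @ u)
                dv_u = (d_v @ u).ravel()
                dh_u = (d_h @ u).ravel()
                dreg = (
                    np.bincount(bid_v_below, lam_v * (2 * dv_u + u2), minlength=nblocks)
                    + np.bincount(bid_v_above, lam_v * (-2 * dv_u + u2), minlength=nblocks)
                    + np.bincount(bid_h_right, lam_h * (2 * dh_u + u2), minlength=nblocks)
                    + np.bincount(bid_h_left, lam_h * (-2 * dh_u + u2), minlength=nblocks)
                )
                deltas[ci] += params.reg_scale * dreg

            best = deltas.argmin(axis=0)
            best_delta = deltas[best, np.arange(nblocks)]
            # strict decrease required; ties keep the current (zero) move
            accept = (best_delta < -params.convergence_tol) & (block_color == col)
            if accept.any():
                changed_any = True
                upd = np.zeros((nblocks, 2))
                upd[accept] = np.asarray(cand)[best[accept]]
                vectors = vectors + upd[bid]
        e = energy(vectors)
        assert e <= trace[-1] * (1 + _ENERGY_SLACK) + _ENERGY_SLACK, (
            "energy increased during optimization"
        )
        trace.append(e)
        it += 1
        if not changed_any:
            if halvings < params.step_refinements:
                step_vox *= 0.5
                halvings += 1
            else:
                converged = True
                break
    return vectors, trace, converged


def register_pair(
    fixed: MultiChannelImage,
    moving: MultiChannelImage,
    classmap: TissueClassMap,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Register ``moving`` onto ``fixed``; returns the field on the level-1 grid.

    The returned displacement field maps fixed-grid points into the moving
    image's physical space; its grid is the fixed grid downscaled by two
    (pyramid stop level one) with doubled spacing.
    """
    params = params or RegistrationParams()
    if fixed.slice_type != moving.slice_type:
        raise ValueError("slice_type mismatch between fixed and moving")
    if fixed.channel_names != moving.channel_names or not np.allclose(
        fixed.channel_weights, moving.channel_weights
    ):
        raise ValueError("fixed and moving must share channel lists and weights")
    if classmap.labels.shape != fixed.grid_shape:
        raise ValueError("class map grid does not match fixed grid")

    H, W = fixed.grid_shape
    # coarsest level: bounded by the configured pyramid depth and a >=4 voxel grid
    max_level = 0
    while (
        max_level < params.pyramid_levels
        and min(H, W) // 2 ** (max_level + 1) >= 4
    ):
        max_level += 1
    stop = params.pyramid_stop_level

    pyr_f = {0: fixed.channels.astype(float)}
    pyr_m = {0: moving.channels.astype(float)}
    lam0 = classmap.weight_image()
    pyr_lam = {0: lam0}
    for lvl in range(1, max_level + 1):
        pyr_f[lvl] = np.stack([_downsample2(c) for c in pyr_f[lvl - 1]])
        pyr_m[lvl] = np.stack([_downsample2(c) for c in pyr_m[lvl - 1]])
        pyr_lam[lvl] = pyr_lam[lvl - 1][::2, ::2]

    vectors = np.zeros(pyr_f[max_level].shape[1:] + (2,))
    result = RegistrationResult(field=None)  # filled below
    for lvl in range(max_level, stop - 1, -1):
        spacing = (fixed.spacing_mm[0] * 2**lvl, fixed.spacing_mm[1] * 2**lvl)
        target_shape = pyr_f[lvl].shape[1:]
        if vectors.shape[:2] != target_shape:
            zoom = (
                target_shape[0] / vectors.shape[0],
                target_shape[1] / vectors.shape[1],
            )
            vectors = np.stack(
                [ndi.zoom(vectors[..., k], zoom, order=1) for k in range(2)], axis=-1
            )
            if params.field_smooth_sigma > 0:
                for k in range(2):
                    vectors[..., k] = ndi.gaussian_filter(
                        vectors[..., k], params.field_smooth_sigma
                    )
        vectors, trace, conv = _optimize_level(
            pyr_f[lvl], pyr_m[lvl], fixed.channel_weights, moving.backgrounds,
            pyr_lam[lvl], spacing, vectors, params,
        )
        result.energy_traces[lvl] = trace
        if not conv:
            result.converged = False
            result.warnings.append(f"level {lvl}: max iterations reached")

    stop_spacing = (fixed.spacing_mm[0] * 2**stop, fixed.spacing_mm[1] * 2**stop)
    result.field = DisplacementField(vectors, stop_spacing)
    return result
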