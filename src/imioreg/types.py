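"""Core in-memory containers shared by all pipeline stages.

Conventions used throughout the package:

* images are 2D numpy arrays indexed ``[row, col]``;
* physical coordinates are millimetres, with the origin at the centre of
  voxel ``(0, 0)`` and axes parallel to the array axes (row-mm, col-mm);
* displacement fields store vectors in mm, in (row, col) component order,
  and map a point ``p`` of the fixed grid to ``p + v(p)`` in the moving
  image's physical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np

SLICE_TYPES = ("liver", "abdomen", "thigh")


class TissueClass(IntEnum):
    """Coarse elasticity classes used for registration regularization."""

    AIR = 0
    ADIPOSE = 1
    SOFT_TISSUE = 2
    BONE = 3


@dataclass
class CTSlice:
    """A single axial CT slice in Hounsfield units with physical geometry.

    ``flags`` carries QC annotations (e.g. ``"metal_suspect"``); flagged
    slices are never silently dropped, only marked.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    slice_type: str
    subject_id: str = ""
    sex: str = "M"
    origin_mm: tuple[float, float] = (0.0, 0.0)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D slice, got shape {self.pixels.shape}")
        if self.slice_type not in SLICE_TYPES:
            raise ValueError(f"unknown slice_type {self.slice_type!r}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (
            self.shape[0] * self.spacing_mm[0],
            self.shape[1] * self.spacing_mm[1],
        )

    def copy(self, **changes) -> "CTSlice":
        out = replace(self, **changes)
        if "pixels" not in changes:
            out.pixels = self.pixels.copy()
        if "flags" not in changes:
            out.flags = set(self.flags)
        return out


@dataclass
class MaskSet:
    """Named binary masks aligned to one :class:`CTSlice`."""

    masks: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks disagree on grid shape: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class TissueClassMap:
    """Per-voxel elasticity class labels plus the class → weight mapping."""

    labels: np.ndarray
    weights: dict[TissueClass, float]

    def weight_image(self) -> np.ndarray:
        out = np.empty(self.labels.shape, dtype=float)
        for cls, w in self.weights.items():
            out[self.labels == int(cls)] = w
        return out


@dataclass
class MultiChannelImage:
    """Ordered weighted channels (CT first, then masks) for registration."""

    channels: np.ndarray  # (C, H, W) float
    channel_names: list[str]
    channel_weights: np.ndarray  # (C,)
    spacing_mm: tuple[float, float]
    slice_type: str
    subject_id: str = ""
    backgrounds: np.ndarray | None = None  # per-channel out-of-bounds fill

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be a (C, H, W) stack")
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("channel_names length mismatch")
        if self.channel_weights.shape[0] != self.channels.shape[0]:
            raise ValueError("channel_weights length mismatch")
        if np.any(self.channel_weights < 0) or not np.any(self.channel_weights > 0):
            raise ValueError("need non-negative weights with at least one > 0")
        if self.backgrounds is None:
            self.backgrounds = np.zeros(self.channels.shape[0])
        else:
            self.backgrounds = np.asarray(self.backgrounds, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


@dataclass
class DisplacementField:
    """Dense 2D displacement field in millimetres on the fixed-image grid."""

    vectors: np.ndarray  # (H, W, 2) mm, (row, col) components
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 2:
            raise ValueError("vectors must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])

    @classmethod
    def zero(cls, shape: tuple[int, int], spacing_mm) -> "DisplacementField":
        return cls(np.zeros(shape + (2,)), tuple(spacing_mm))


@dataclass
class RegistrationParams:
    """Tunable settings of the discrete multi-resolution optimizer.

    ``step_size`` is expressed in voxels of the current pyramid level;
    ``block_size`` is the edge length (voxels) of the square blocks that
    receive one candidate displacement update per move.
    """

    step_size: float = 0.5
    block_size: int = 16
    update_rule: str = "additive"
    pyramid_levels: int = 8
    pyramid_stop_level: int = 1
    max_iterations_per_level: int = 30
    convergence_tol: float = 1e-6
    reg_scale: float = 0.01
    step_refinements: int = 2  # halvings of step_size after local convergence
    field_smooth_sigma: float = 1.0  # voxels, applied when upsampling a level

    def __post_init__(self) -> None:
        if not (1 <= self.pyramid_stop_level <= self.pyramid_levels):
            raise ValueError("need 1 <= pyramid_stop_level <= pyramid_levels")
        if self.step_size <= 0 or self.block_size < 1:
            raise ValueError("step_size > 0 and block_size >= 1 required")
        if self.update_rule != "additive":
            raise ValueError(f"unsupported update rule {self.update_rule!r}")


@dataclass
class EvalReport:
    """Inverse-consistency summary for one registered image pair."""

    vme_mm: float
    ime_hu: float
    n_folds: float
    omega_size: int
    runtime_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.omega_size <= 0:
            raise ValueError("omega_size must be positive")
        for name in ("vme_mm", "ime_hu", "n_folds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class JacobianMap:
    """Jacobian determinant of a transform and its natural log.

    ``log_det`` is finite exactly where ``det > 0``; elsewhere it is NaN,
    marking locally non-invertible (folded or degenerate) voxels.
    """

    det: np.ndarray
    log_det: np.ndarray


@dataclass
class BetaMap:
    """Per-voxel OLS intercept/slope/R² maps for one covariate."""

    beta0: np.ndarray
    beta1: np.ndarray
    r2: np.ndarray
    n: int
    covariate: str = ""
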