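"""Default thresholds, weights and geometry parameters.

Everything a site might want to tune lives here rather than hard-coded in
the operations: HU thresholds for the classical masks, morphology radii,
per-slice registration channel weights, the elasticity weight map, and the
phantom population parameters.  All values can be overridden through the
JSON config accepted by the CLI.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any

from .types import TissueClass

# ---------------------------------------------------------------------------
# Geometry standardization
# ---------------------------------------------------------------------------
TARGET_FOV_MM = 500.0
TARGET_GRID = 512
HU_TRUNCATE = 1024.0
HU_FLOOR = -1024.0
METAL_HU = 2000.0
METAL_VOXEL_COUNT = 50  # >= this many voxels above METAL_HU -> flag

# ---------------------------------------------------------------------------
# Classical mask thresholds (HU) and morphology radii (voxels)
# ---------------------------------------------------------------------------
BODY_THRESHOLD_HU = -190.0
VERTEBRA_THRESHOLD_HU = 200.0
BONE_THRESHOLD_HU = 200.0
LEAN_WINDOW_HU = (-29.0, 150.0)

BODY_CLOSING_RADIUS = 3
VERTEBRA_OPENING_RADIUS = 1
ISAT_CLOSING_RADIUS = 8  # ~8 mm at the standard 0.977 mm pitch

# ---------------------------------------------------------------------------
# Tissue-class regularization map
# ---------------------------------------------------------------------------
# Class boundaries reuse the printed mask windows: air/adipose at the body
# threshold, adipose/soft at the lean-window floor, soft/bone at its ceiling.
CLASS_BOUNDS_HU = {"air_adipose": -190.0, "adipose_soft": -30.0, "soft_bone": 150.0}
REGULARIZATION_WEIGHTS = {
    TissueClass.AIR: 0.05,
    TissueClass.ADIPOSE: 0.05,
    TissueClass.SOFT_TISSUE: 0.05,
    TissueClass.BONE: 0.1,
}

# ---------------------------------------------------------------------------
# Multi-channel similarity weights per slice type (CT channel first)
# ---------------------------------------------------------------------------
CHANNEL_WEIGHTS = {
    "liver": {"ct": 0.5, "liver": 0.1, "spleen": 0.1, "body": 0.15, "vertebra": 0.15},
    "abdomen": {"ct": 0.4, "body": 0.1, "vertebra": 0.2, "muscle": 0.2, "isat": 0.1},
    "thigh": {"ct": 0.5, "body": 0.1, "bone": 0.2, "lean": 0.2},
}

# CT channel is mapped affinely from [-1024, 1024] HU onto [0, 1] so that the
# channel weights compare like with like (masks are already {0, 1}).
CT_NORM_RANGE_HU = (-1024.0, 1024.0)

# ---------------------------------------------------------------------------
# Phantom population (free parameters of the synthetic cohorts; documented
# here, not hard-coded in the generator)
# ---------------------------------------------------------------------------
PHANTOM_POPULATION = {
    "body_scale_sd": 0.04,       # multiplicative jitter on body semi-axes
    "structure_scale_sd": 0.05,  # per-structure semi-axis jitter
    "center_jitter_mm": 3.0,     # per-structure centre jitter
    "covariate_mean": 27.0,      # BMI-like covariate (kg/m^2)
    "covariate_sd": 4.0,
    "age_mean": 58.0,            # years, carried as a second covariate
    "age_sd": 4.4,
    "area_noise_frac": 0.03,     # residual noise on a planted-effect area
}
PHANTOM_HU_NOISE_SD = 12.0  # additive Gaussian noise, HU
PHANTOM_SMOOTH_SIGMA = 0.6  # voxels, mimics a medium-smooth recon kernel

MEASUREMENT_COLUMNS = [
    "liver",
    "spleen",
    "abdominal_muscle",
    "VAT",
    "SAT",
    "thigh_SAT",
    "IMAT",
    "thigh_muscle",
    "liver_fat_HU",
]
COVARIATE_COLUMNS = ["age", "BMI"]

# Measurement columns entering template selection, per slice type.
TEMPLATE_COLUMNS = {
    "liver": ["spleen", "liver", "VAT", "SAT"],
    "abdomen": ["VAT", "SAT", "abdominal_muscle"],
    "thigh": ["thigh_SAT", "thigh_muscle"],
}


def default_config() -> dict[str, Any]:
    """One nested dict with every tunable, suitable for JSON round-trip."""
    return copy.deepcopy(
        {
            "standardize": {
                "target_fov_mm": TARGET_FOV_MM,
                "target_grid": TARGET_GRID,
                "hu_truncate": HU_TRUNCATE,
                "metal_hu": METAL_HU,
                "metal_voxel_count": METAL_VOXEL_COUNT,
            },
            "masks": {
                "body_threshold_hu": BODY_THRESHOLD_HU,
                "vertebra_threshold_hu": VERTEBRA_THRESHOLD_HU,
                "bone_threshold_hu": BONE_THRESHOLD_HU,
                "lean_window_hu": list(LEAN_WINDOW_HU),
                "body_closing_radius": BODY_CLOSING_RADIUS,
                "vertebra_opening_radius": VERTEBRA_OPENING_RADIUS,
                "isat_closing_radius": ISAT_CLOSING_RADIUS,
            },
            "regularization": {
                "class_bounds_hu": dict(CLASS_BOUNDS_HU),
                "weights": {c.name.lower(): w for c, w in REGULARIZATION_WEIGHTS.items()},
            },
            "channels": copy.deepcopy(CHANNEL_WEIGHTS),
            "registration": {
                "step_size": 0.5,
                "block_size": 16,
                "update_rule": "additive",
                "pyramid_levels": 8,
                "pyramid_stop_level": 1,
                "max_iterations_per_level": 30,
                "reg_scale": 0.01,
            },
            "phantom": {
                "population": dict(PHANTOM_POPULATION),
                "hu_noise_sd": PHANTOM_HU_NOISE_SD,
                "smooth_sigma": PHANTOM_SMOOTH_SIGMA,
            },
            "evaluation": {"omega_erosion_voxels": 1},
        }
    )


def config_hash(config: dict[str, Any]) -> str:
    """Stable fingerprint of a config dict, recorded in every manifest."""
    payload = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
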