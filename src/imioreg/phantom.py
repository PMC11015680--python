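"""Synthetic 3-slice CT phantoms with known geometry, warps and effects.

The generator emulates the three single-slice body-composition stations
(liver, abdomen, thigh) as compositions of rotated ellipses painted with
realistic Hounsfield levels (air ~ -1000, adipose ~ -100, lean ~ 40-60,
cortical bone >= 200), plus additive Gaussian noise and a mild smoothing
that stands in for a medium-smooth reconstruction kernel.  Because every
structure is analytic, each subject comes with exact ground-truth masks,
tissue areas, and — via :func:`apply_synthetic_warp` — dense ground-truth
displacement fields, so the registration and voxel-wise statistics stages
can be validated without access to any cohort data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import config as cfg
from .types import CTSlice, DisplacementField, MaskSet, SLICE_TYPES

# Canonical tissue HU levels.  The ordering air < fat < lean < bone is a
# validated invariant of every spec.
DEFAULT_HU_MEANS = {
    "air": -1000.0,
    "fat": -100.0,
    "lean": 50.0,
    "bone": 400.0,
    "lung": -800.0,
    "liver": 55.0,
    "spleen": 50.0,
    "muscle": 45.0,
    "vat": -95.0,
    "marrow": -80.0,
    "gas": -1000.0,
    "cortical": 500.0,
    "table": -50.0,
}

# Structures that may carry a planted covariate effect (single primitive
# ellipse whose area maps directly onto a measurement column).
EFFECT_STRUCTURES = {"liver": "liver", "spleen": "spleen", "imat": "IMAT"}


@dataclass
class PhantomSpec:
    """Full description of one synthetic slice (geometry, HU, noise, seed)."""

    slice_type: str
    grid_size: int = 512
    fov_mm: float = 500.0
    organ_geometry: dict = dc_field(default_factory=dict)
    hu_means: dict = dc_field(default_factory=dict)
    hu_noise_sd: float = cfg.PHANTOM_HU_NOISE_SD
    smooth_sigma: float = cfg.PHANTOM_SMOOTH_SIGMA
    seed: int = 0
    add_table: bool = False
    metal_voxels: int = 0  # plant this many >2000 HU voxels (flag testing)

    def __post_init__(self) -> None:
        if self.slice_type not in SLICE_TYPES:
            raise ValueError(f"unknown slice_type {self.slice_type!r}")
        hu = dict(DEFAULT_HU_MEANS)
        hu.update(self.hu_means)
        self.hu_means = hu
        order = [hu["air"], hu["fat"], hu["lean"], hu["bone"]]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(f"hu_means must satisfy air < fat < lean < bone, got {order}")
        if not self.organ_geometry:
            self.organ_geometry = default_geometry(self.slice_type)
        _validate_geometry(self.slice_type, self.organ_geometry, self.fov_mm)

    @property
    def spacing_mm(self) -> float:
        return self.fov_mm / self.grid_size


@dataclass
class PhantomSubject:
    subject_id: str
    sex: str
    slices: dict[str, CTSlice]
    truth_masks: dict[str, MaskSet]
    truth_areas: dict[str, float]  # cm^2, mask voxel-count x voxel-area
    covariates: dict[str, float]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ell(cy, cx, ay, ax, rot=0.0):
    return {"center": (float(cy), float(cx)), "semi": (float(ay), float(ax)), "rot": float(rot)}


def _shrink(e, t):
    """Shrink both semi-axes of an ellipse dict by ``t`` mm."""
    ay, ax = e["semi"]
    return {**e, "semi": (max(ay - t, 1.0), max(ax - t, 1.0))}


def default_geometry(slice_type: str) -> dict:
    """Base anatomy of each station, in mm on a 500 mm field of view."""
    c = 250.0
    if slice_type == "liver":
        body = _ell(c, c, 130, 170)
        return {
            "body": body,
            "interior": _shrink(body, 14),
            "liver": _ell(235, 180, 58, 78, 0.25),
            "spleen": _ell(245, 345, 26, 34, -0.2),
            "lung_l": _ell(172, 185, 28, 38),
            "lung_r": _ell(174, 320, 26, 34),
            "vertebra": _ell(330, 250, 20, 22),
        }
    if slice_type == "abdomen":
        body = _ell(c, c, 125, 175)
        muscle_outer = _shrink(body, 13)
        muscle_inner = _shrink(muscle_outer, 11)
        return {
            "body": body,
            "muscle_outer": muscle_outer,
            "muscle_inner": muscle_inner,
            "organ_1": _ell(215, 205, 30, 36, 0.3),
            "organ_2": _ell(230, 300, 26, 30, -0.4),
            "gas_1": _ell(180, 250, 11, 15),
            "gas_2": _ell(205, 155, 8, 10),
            "vertebra": _ell(322, 250, 18, 20),
        }
    if slice_type == "thigh":
        out = {}
        for side, cx in (("l", 160.0), ("r", 340.0)):
            thigh = _ell(c, cx, 80, 80)
            out[f"thigh_{side}"] = thigh
            out[f"lean_{side}"] = _shrink(thigh, 13)
            out[f"bone_{side}"] = _ell(c, cx, 18, 18)
            out[f"marrow_{side}"] = _ell(c, cx, 12, 12)
            out[f"imat_{side}"] = _ell(c - 25, cx + (22 if side == "l" else -22), 8, 6)
        return out
    raise ValueError(slice_type)


# Containment requirements (structure -> enclosing structure) checked at
# spec validation time; a violation is rejected naming the structure.
_CONTAINERS = {
    "liver": {
        "interior": "body", "liver": "body", "spleen": "body",
        "lung_l": "body", "lung_r": "body", "vertebra": "body",
    },
    "abdomen": {
        "muscle_outer": "body", "muscle_inner": "muscle_outer",
        "organ_1": "muscle_inner", "organ_2": "muscle_inner",
        "gas_1": "muscle_inner", "gas_2": "muscle_inner",
        "vertebra": "body",
    },
    "thigh": {
        "lean_l": "thigh_l", "bone_l": "lean_l", "marrow_l": "bone_l", "imat_l": "lean_l",
        "lean_r": "thigh_r", "bone_r": "lean_r", "marrow_r": "bone_r", "imat_r": "lean_r",
    },
}


def _boundary_points(e, n=64):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ay, ax = e["semi"]
    cy, cx = e["center"]
    rot = e["rot"]
    u, v = ax * np.cos(t), ay * np.sin(t)
    x = cx + u * math.cos(rot) - v * math.sin(rot)
    y = cy + u * math.sin(rot) + v * math.cos(rot)
    return y, x


def _inside(e, y, x, tol=1e-9):
    cy, cx = e["center"]
    ay, ax = e["semi"]
    rot = e["rot"]
    dy, dx = y - cy, x - cx
    u = dx * math.cos(rot) + dy * math.sin(rot)
    v = -dx * math.sin(rot) + dy * math.cos(rot)
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0 + tol


def _validate_geometry(slice_type, geometry, fov_mm):
    required = set(default_geometry(slice_type))
    missing = required - set(geometry)
    if missing:
        raise ValueError(f"geometry missing structures: {sorted(missing)}")
    outer = ["body"] if slice_type != "thigh" else ["thigh_l", "thigh_r"]
    for name in outer:
        y, x = _boundary_points(geometry[name])
        if (y < 0).any() or (x < 0).any() or (y > fov_mm).any() or (x > fov_mm).any():
            raise ValueError(f"structure {name!r} extends outside the field of view")
    for name, container in _CONTAINERS[slice_type].items():
        y, x = _boundary_points(geometry[name])
        if not np.all(_inside(geometry[container], y, x, tol=1e-6)):
            raise ValueError(f"structure {name!r} not contained in {container!r}")


def _ellipse_mask(shape, spacing, e):
    yy = np.arange(shape[0])[:, None] * spacing
    xx = np.arange(shape[1])[None, :] * spacing
    return _inside(e, yy, xx)


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def generate_subject(spec: PhantomSpec, subject_id: str = "S000", sex: str = "M") -> PhantomSubject:
    """Render one slice from its spec: paint, add noise, derive truth masks.

    Noise is additive Gaussian in HU; the same seed reproduces the pixel
    array bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.grid_size, spec.grid_size)
    sp = spec.spacing_mm
    g = spec.organ_geometry
    hu = spec.hu_means

    m = {name: _ellipse_mask(shape, sp, e) for name, e in g.items()}
    pixels = np.full(shape, hu["air"])

    if spec.slice_type == "liver":
        pixels[m["body"]] = hu["fat"]
        pixels[m["interior"]] = hu["lean"]
        pixels[m["lung_l"] | m["lung_r"]] = hu["lung"]
        pixels[m["liver"]] = hu["liver"]
        pixels[m["spleen"]] = hu["spleen"]
        pixels[m["vertebra"]] = hu["bone"]
        masks = {
            "body": m["body"],
            "liver": m["liver"],
            "spleen": m["spleen"],
            "vertebra": m["vertebra"],
            "lung": m["lung_l"] | m["lung_r"],
        }
    elif spec.slice_type == "abdomen":
        pixels[m["body"]] = hu["fat"]
        pixels[m["muscle_outer"]] = hu["muscle"]
        pixels[m["muscle_inner"]] = hu["vat"]
        organs = m["organ_1"] | m["organ_2"]
        gas = m["gas_1"] | m["gas_2"]
        pixels[organs] = hu["lean"]
        pixels[gas] = hu["gas"]
        pixels[m["vertebra"]] = hu["bone"]
        muscle = m["muscle_outer"] & ~m["muscle_inner"] & ~m["vertebra"]
        masks = {
            "body": m["body"],
            "muscle": muscle,
            "vertebra": m["vertebra"],
            "VAT": m["muscle_inner"] & ~(organs | gas | m["vertebra"]),
            "SAT": m["body"] & ~m["muscle_outer"],
            "isat": m["muscle_inner"],
        }
    else:  # thigh
        circles = m["thigh_l"] | m["thigh_r"]
        lean_c = m["lean_l"] | m["lean_r"]
        bone = m["bone_l"] | m["bone_r"]
        marrow = m["marrow_l"] | m["marrow_r"]
        imat = m["imat_l"] | m["imat_r"]
        pixels[circles] = hu["fat"]
        pixels[lean_c] = hu["lean"]
        pixels[imat] = hu["fat"]
        pixels[bone] = hu["cortical"]
        pixels[marrow] = hu["marrow"]
        masks = {
            "body": circles,
            "bone": bone,
            "lean": lean_c & ~(bone | imat),
            "thigh_SAT": circles & ~lean_c,
            "IMAT": imat,
        }

    if spec.add_table:
        fov = spec.fov_mm
        table = _ellipse_mask(shape, sp, _ell(0.955 * fov, fov / 2, 8, 0.38 * fov))
        table &= ~masks["body"]
        pixels = np.where(table, hu["table"], pixels)

    if spec.smooth_sigma > 0:
        pixels = ndi.gaussian_filter(pixels, spec.smooth_sigma)
    if spec.hu_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.hu_noise_sd, shape)

    if spec.metal_voxels > 0:
        # plant bright voxels inside the body to exercise the metal flag
        by, bx = np.nonzero(masks["body"])
        idx = rng.choice(by.size, size=min(spec.metal_voxels, by.size), replace=False)
        pixels[by[idx], bx[idx]] = 3000.0

    pixels = np.clip(pixels, cfg.HU_FLOOR, None)

    ct = CTSlice(
        pixels=pixels,
        spacing_mm=(sp, sp),
        slice_type=spec.slice_type,
        subject_id=subject_id,
        sex=sex,
    )
    voxel_cm2 = sp * sp / 100.0
    areas = {name: float(mask.sum()) * voxel_cm2 for name, mask in masks.items()}
    return PhantomSubject(
        subject_id=subject_id,
        sex=sex,
        slices={spec.slice_type: ct},
        truth_masks={spec.slice_type: MaskSet(masks, {k: "truth" for k in masks})},
        truth_areas=areas,
        covariates={},
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _jitter_geometry(slice_type, rng, population, effect_scale=None):
    """Per-subject random geometry drawn around the default anatomy."""
    g = default_geometry(slice_type)
    body_s = float(np.clip(rng.normal(1.0, population["body_scale_sd"]), 0.85, 1.15))
    jit = population["center_jitter_mm"]
    struct_sd = population["structure_scale_sd"]

    def scale_e(e, s, jitter=True):
        ay, ax = e["semi"]
        cy, cx = e["center"]
        if jitter:
            cy += rng.normal(0, jit)
            cx += rng.normal(0, jit)
        return {**e, "semi": (ay * s, ax * s), "center": (cy, cx)}

    out = {}
    if slice_type == "thigh":
        for side in ("l", "r"):
            s_side = body_s * float(np.clip(rng.normal(1.0, struct_sd), 0.85, 1.15))
            thigh = scale_e(g[f"thigh_{side}"], s_side, jitter=False)
            out[f"thigh_{side}"] = thigh
            out[f"lean_{side}"] = _shrink(thigh, 13 * s_side)
            for name in (f"bone_{side}", f"marrow_{side}", f"imat_{side}"):
                s = s_side * float(np.clip(rng.normal(1.0, struct_sd), 0.85, 1.15))
                e = dict(g[name])
                e["semi"] = (e["semi"][0] * s, e["semi"][1] * s)
                if name.startswith("imat"):
                    cy, cx = e["center"]
                    e["center"] = (cy + rng.normal(0, jit), cx + rng.normal(0, jit))
                out[name] = e
    else:
        body = scale_e(g["body"], body_s, jitter=False)
        out["body"] = body
        if slice_type == "liver":
            out["interior"] = _shrink(body, 14 * body_s)
            inner = ("liver", "spleen", "lung_l", "lung_r", "vertebra")
        else:
            out["muscle_outer"] = _shrink(body, 13 * body_s)
            out["muscle_inner"] = _shrink(out["muscle_outer"], 11 * body_s)
            inner = ("organ_1", "organ_2", "gas_1", "gas_2", "vertebra")
        for name in inner:
            s = body_s * float(np.clip(rng.normal(1.0, struct_sd), 0.85, 1.15))
            out[name] = scale_e(g[name], s, jitter=not name.startswith("vertebra"))
    if effect_scale:
        for name, s in effect_scale.items():
            e = out[name]
            out[name] = {**e, "semi": (e["semi"][0] * s, e["semi"][1] * s)}
    _repair_containment(slice_type, out)
    return out


def _repair_containment(slice_type, geo, max_rounds: int = 60) -> None:
    """Deterministically nudge jittered structures back inside their container.

    Each offending structure is pulled 10% towards its container's centre
    and shrunk by 3% per round; jitter magnitudes are small, so this
    converges in a few rounds and leaves well-placed structures untouched.
    """
    for name, container in _CONTAINERS[slice_type].items():
        for _ in range(max_rounds):
            y, x = _boundary_points(geo[name])
            if np.all(_inside(geo[container], y, x, tol=1e-6)):
                break
            e = geo[name]
            cy, cx = e["center"]
            ky, kx = geo[container]["center"]
            geo[name] = {
                **e,
                "center": (cy + 0.1 * (ky - cy), cx + 0.1 * (kx - cx)),
                "semi": (e["semi"][0] * 0.97, e["semi"][1] * 0.97),
            }
        else:
            raise ValueError(f"could not fit structure {name!r} inside {container!r}")


def generate_cohort(
    n: int,
    population: dict | None = None,
    effect: dict | None = None,
    seed: int = 0,
    grid_size: int = 512,
    slice_types=SLICE_TYPES,
    hu_noise_sd: float = cfg.PHANTOM_HU_NOISE_SD,
    cohort: str = "PHANTOM",
):
    """Generate ``n`` subjects (all requested stations) plus the measurements table.

    ``effect`` plants a linear link between a covariate and one structure's
    area: ``{"structure": "liver", "covariate": "BMI", "slope": cm2_per_unit,
    "noise_sd": cm2}``.  With zero geometry noise in ``population`` the
    structure's area is then an exact linear (plus stated noise) function of
    the covariate.

    Returns ``(subjects, measurements)`` where ``measurements`` is a
    DataFrame with exactly the explicit-measurement columns (areas in cm²,
    liver fat attenuation in HU) plus covariates.
    """
    if n < 2:
        raise ValueError("need n >= 2 for cohort statistics")
    population = {**cfg.PHANTOM_POPULATION, **(population or {})}
    if effect is not None and effect["structure"] not in EFFECT_STRUCTURES:
        raise ValueError(
            f"effect structure {effect['structure']!r} not in {sorted(EFFECT_STRUCTURES)}"
        )

    root = np.random.SeedSequence(seed)
    children = root.spawn(n + 1)
    cov_rng = np.random.default_rng(children[0])
    bmi = cov_rng.normal(population["covariate_mean"], population["covariate_sd"], n)
    age = cov_rng.normal(population["age_mean"], population["age_sd"], n)

    subjects: list[PhantomSubject] = []
    rows = []
    for k in range(n):
        rng = np.random.default_rng(children[k + 1])
        sid = f"P{k:03d}"
        sex = "M" if k % 2 == 0 else "F"
        covs = {"age": float(age[k]), "BMI": float(bmi[k])}

        effect_scale = None
        if effect is not None:
            x = covs[effect.get("covariate", "BMI")]
            xref = population["covariate_mean"] if effect.get("covariate", "BMI") == "BMI" \
                else population["age_mean"]
            target = effect["slope"] * (x - xref) + rng.normal(0.0, effect.get("noise_sd", 0.0))
            # convert the cm^2 offset into a semi-axis scale of the base ellipse
            struct = effect["structure"]
            slice_of = {"liver": "liver", "spleen": "liver", "imat": "thigh"}[struct]
            base = default_geometry(slice_of)
            if struct == "imat":
                a0 = sum(
                    math.pi * base[f"imat_{s}"]["semi"][0] * base[f"imat_{s}"]["semi"][1]
                    for s in ("l", "r")
                ) / 100.0
                names = ["imat_l", "imat_r"]
            else:
                a0 = math.pi * base[struct]["semi"][0] * base[struct]["semi"][1] / 100.0
                names = [struct]
            s = math.sqrt(max(1.0 + target / a0, 0.1))
            effect_scale = {nm: s for nm in names}

        subj = PhantomSubject(sid, sex, {}, {}, {}, covs)
        for st in slice_types:
            geo = _jitter_geometry(st, rng, population, effect_scale)
            spec = PhantomSpec(
                slice_type=st,
                grid_size=grid_size,
                organ_geometry=geo,
                hu_noise_sd=hu_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            one = generate_subject(spec, sid, sex)
            subj.slices[st] = one.slices[st]
            subj.truth_masks[st] = one.truth_masks[st]
            subj.truth_areas.update(
                {f"{st}:{k2}": v for k2, v in one.truth_areas.items()}
            )
        subjects.append(subj)
        rows.append(_measure_row(subj, cohort))
    meas = pd.DataFrame(rows)
    return subjects, meas


def _measure_row(subj: PhantomSubject, cohort: str) -> dict:
    """Explicit measurements (cm², HU) from the truth masks of one subject."""
    row = {"subject_id": subj.subject_id, "sex": subj.sex, "cohort": cohort}
    a = subj.truth_areas

    def get(key, default=np.nan):
        return a.get(key, default)

    row["liver"] = get("liver:liver")
    row["spleen"] = get("liver:spleen")
    row["abdominal_muscle"] = get("abdomen:muscle")
    row["VAT"] = get("abdomen:VAT")
    row["SAT"] = get("abdomen:SAT")
    row["thigh_SAT"] = get("thigh:thigh_SAT")
    row["IMAT"] = get("thigh:IMAT")
    row["thigh_muscle"] = get("thigh:lean")
    if "liver" in subj.slices and "liver" in subj.truth_masks["liver"].masks:
        liver_mask = subj.truth_masks["liver"]["liver"]
        row["liver_fat_HU"] = float(subj.slices["liver"].pixels[liver_mask].mean())
    else:
        row["liver_fat_HU"] = np.nan
    row.update(subj.covariates)
    return row


# ---------------------------------------------------------------------------
# Ground-truth warps
# ---------------------------------------------------------------------------

def _bulge_profile(dy, dx, amplitude, sigma):
    """Radial Gaussian bulge with peak displacement ``amplitude`` at r = sigma."""
    r2 = dy * dy + dx * dx
    f = (amplitude / sigma) * np.exp(0.5 * (1.0 - r2 / sigma**2))
    return f


def bulge_jacobian_analytic(shape, spacing_mm, center_mm, amplitude_mm, sigma_mm):
    """Closed-form Jacobian determinant of the radial bulge transform."""
    yy = np.arange(shape[0])[:, None] * spacing_mm - center_mm[0]
    xx = np.arange(shape[1])[None, :] * spacing_mm - center_mm[1]
    r2 = yy * yy + xx * xx
    f = (amplitude_mm / sigma_mm) * np.exp(0.5 * (1.0 - r2 / sigma_mm**2))
    return (1.0 + f) * (1.0 + f * (1.0 - r2 / sigma_mm**2))


def synthetic_field(slice_shape, spacing_mm, warp: dict) -> DisplacementField:
    """Build the analytic displacement field (mm) for a warp description."""
    sp = spacing_mm[0]
    v = np.zeros(slice_shape + (2,))
    kinds = warp if isinstance(warp, (list, tuple)) else [warp]
    for w in kinds:
        if w["kind"] == "translation":
            v[..., 0] += w["offset_mm"][0]
            v[..., 1] += w["offset_mm"][1]
        elif w["kind"] == "bulge":
            cy, cx = w["center_mm"]
            amp, sig = w["amplitude_mm"], w["sigma_mm"]
            yy = np.arange(slice_shape[0])[:, None] * sp - cy
            xx = np.arange(slice_shape[1])[None, :] * sp - cx
            f = _bulge_profile(yy, xx, amp, sig)
            v[..., 0] += f * yy
            v[..., 1] += f * xx
        else:
            raise ValueError(f"unknown warp kind {w['kind']!r}")
    return DisplacementField(v, tuple(spacing_mm))


def apply_synthetic_warp(ct: CTSlice, warp, seed: int = 0):
    """Warp a slice by a smooth parametric deformation with known inverse data.

    Returns ``(warped_slice, truth_field)`` where the field maps points of
    the *warped* image back into the source image, i.e. exactly the field a
    registration with ``fixed=warped, moving=source`` should recover.
    Warps whose analytic transform folds (Jacobian determinant <= 0
    anywhere) are rejected.
    """
    from .register import warp_image  # local import avoids a cycle at import time
    from .transform_eval import jacobian_determinant

    field = synthetic_field(ct.shape, ct.spacing_mm, warp)
    kinds = warp if isinstance(warp, (list, tuple)) else [warp]
    for w in kinds:
        if w["kind"] == "bulge":
            amp, sig = w["amplitude_mm"], w["sigma_mm"]
            if amp >= sig * math.e / 2.0:
                raise ValueError(
                    f"bulge amplitude {amp} mm folds (needs amplitude < sigma*e/2 = "
                    f"{sig * math.e / 2.0:.2f} mm)"
                )
    det = jacobian_determinant(field).det
    if np.any(det <= 0):
        raise ValueError("warp folds: analytic field has non-positive Jacobian")

    background = float(np.min(ct.pixels))
    warped = warp_image(ct.pixels, field, interpolation="linear", background=background)
    out = ct.copy(pixels=warped)
    return out, field
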