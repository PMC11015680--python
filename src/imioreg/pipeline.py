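"""End-to-end phantom study: generate, preprocess, register, evaluate, analyze.

:func:`run_phantom_study` is the in-memory driver used by the tests and by
the reproduction script; the ``stage_*`` functions are the disk-backed
equivalents behind the CLI subcommands, operating on a run directory laid
out by :func:`build_cohort_dir` (NIfTI images and masks, a CSV measurement
table, and a JSON manifest carrying paths, template ids and the config
fingerprint).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import config as cfg
from . import imiomics, io, phantom, preprocess, transform_eval
from .register import (
    RegistrationParams,
    downsample,
    downsample_mask,
    register_pair,
    resample_via_field,
)
from .types import CTSlice, DisplacementField, MaskSet, SLICE_TYPES

log = logging.getLogger(__name__)

EVAL_COLUMNS = ["cohort", "slice", "sex", "subject", "vme_mm", "ime_hu", "n_folds", "runtime_s"]


def _omega_from_body(body: np.ndarray, levels: int = 1, erosion: int = 1) -> np.ndarray:
    """Body region at the field grid, eroded to dodge border interpolation."""
    m = downsample_mask(body, levels)
    if erosion > 0:
        m = ndi.binary_erosion(m, iterations=erosion)
    return m


@dataclass
class StudyResult:
    measurements: pd.DataFrame
    templates: dict[str, dict[str, str]]  # slice_type -> group key -> subject_id
    evals: pd.DataFrame
    group_means: pd.DataFrame  # per (slice, sex): mean vme/ime over pairs
    betamaps: dict = dc_field(default_factory=dict)  # (slice, group, column) -> maps
    group_maps: dict = dc_field(default_factory=dict)
    correlations: pd.DataFrame | None = None
    registrations: dict = dc_field(default_factory=dict)


def run_phantom_study(
    n: int = 10,
    seed: int = 0,
    grid_size: int = 256,
    slice_types=SLICE_TYPES,
    population: dict | None = None,
    effect: dict | None = None,
    params: RegistrationParams | None = None,
    group_by_sex: bool = True,
    hu_noise_sd: float = cfg.PHANTOM_HU_NOISE_SD,
    with_imiomics: bool = True,
) -> StudyResult:
    """Full synthetic study on one in-memory cohort.

    Mirrors the production flow: per-sex template selection by summed |z|,
    forward and reverse registration of every subject to its template,
    inverse-consistency evaluation over the eroded body region, then
    voxel-wise regressions of deformed HU and log-Jacobian stacks against
    the explicit measurements.
    """
    params = params or RegistrationParams()
    subjects, meas = phantom.generate_cohort(
        n, population=population, effect=effect, seed=seed,
        grid_size=grid_size, slice_types=slice_types, hu_noise_sd=hu_noise_sd,
    )

    # preprocess every slice; organ masks come from the phantom ground truth
    proc: dict[tuple[str, str], tuple] = {}
    for subj in subjects:
        for st in slice_types:
            ext = _external_masks(subj.truth_masks[st], st)
            std, masks, classmap = preprocess.preprocess_subject(
                subj.slices[st], ext, target_grid=grid_size
            )
            proc[(subj.subject_id, st)] = (std, masks, classmap)

    groups = ["M", "F"] if group_by_sex else [None]
    templates: dict[str, dict[str, str]] = {st: {} for st in slice_types}
    eval_rows = []
    result = StudyResult(meas, templates, None, None)

    for st in slice_types:
        for sex in groups:
            gkey = sex or "ALL"
            group_filter = {"sex": sex} if sex else None
            tid = imiomics.select_template(meas, st, group_filter)
            templates[st][gkey] = tid
            members = meas if sex is None else meas[meas["sex"] == sex]
            sids = list(members["subject_id"])

            t_std, t_masks, t_classmap = proc[(tid, st)]
            t_chan = preprocess.assemble_channels(t_std, t_masks)
            omega_t = _omega_from_body(t_masks["body"])

            hu_stack, logjac_stack, stack_ids = [], [], []
            # template contributes itself through the identity transform
            hu_stack.append(downsample(t_std.pixels, 1))
            logjac_stack.append(np.zeros(omega_t.shape))
            stack_ids.append(tid)

            for sid in sids:
                if sid == tid:
                    continue
                s_std, s_masks, s_classmap = proc[(sid, st)]
                s_chan = preprocess.assemble_channels(s_std, s_masks)
                t0 = time.perf_counter()
                fwd = register_pair(t_chan, s_chan, t_classmap, params)
                rev = register_pair(s_chan, t_chan, s_classmap, params)
                dt = time.perf_counter() - t0
                omega_s = _omega_from_body(s_masks["body"])
                rep = transform_eval.pair_consistency(
                    fwd.field, rev.field, t_std, s_std, omega_t, omega_s,
                    runtime_s=dt,
                )
                eval_rows.append(
                    dict(
                        cohort="PHANTOM", slice=st, sex=sex or "ALL", subject=sid,
                        vme_mm=rep.vme_mm, ime_hu=rep.ime_hu,
                        n_folds=rep.n_folds, runtime_s=dt,
                    )
                )
                result.registrations[(st, sid)] = (fwd, rev)
                hu_stack.append(
                    resample_via_field(
                        s_std.pixels, s_std.spacing_mm, fwd.field,
                        background=float(s_std.pixels.min()),
                    )
                )
                jac = transform_eval.jacobian_determinant(fwd.field)
                logjac_stack.append(jac.log_det)
                stack_ids.append(sid)

            if with_imiomics and len(stack_ids) >= 3:
                rows = meas.set_index("subject_id").loc[stack_ids].reset_index()
                hu_arr = np.stack(hu_stack)
                lj_arr = np.stack(logjac_stack)
                result.betamaps[(st, gkey)] = imiomics.run_group_regressions(
                    hu_arr, lj_arr, rows, st, omega_t
                )
                result.group_maps[(st, gkey)] = transform_eval.group_statistics(
                    registered_hu=hu_arr, log_jacs=lj_arr
                )

    result.evals = pd.DataFrame(eval_rows, columns=EVAL_COLUMNS)
    result.group_means = (
        result.evals.groupby(["slice", "sex"])[["vme_mm", "ime_hu", "n_folds"]]
        .mean()
        .reset_index()
    )
    if with_imiomics:
        result.correlations = imiomics.correlation_matrix(meas, _populated_columns(meas))
    return result


def _external_masks(truth: MaskSet, slice_type: str) -> dict[str, np.ndarray]:
    """Ground-truth stand-ins for the learned organ segmentations."""
    if slice_type == "liver":
        return {"liver": truth["liver"], "spleen": truth["spleen"]}
    if slice_type == "abdomen":
        return {"muscle": truth["muscle"]}
    return {}


# ---------------------------------------------------------------------------
# Disk-backed stages (CLI)
# ---------------------------------------------------------------------------

def build_cohort_dir(
    out_dir,
    n: int,
    seed: int = 0,
    grid_size: int = 256,
    slice_types=SLICE_TYPES,
    population: dict | None = None,
    effect: dict | None = None,
) -> dict:
    """Generate a cohort and write images, truth masks, table, manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    subjects, meas = phantom.generate_cohort(
        n, population=population, effect=effect, seed=seed,
        grid_size=grid_size, slice_types=slice_types,
    )
    io.write_measurements(meas, out / "measurements.csv")

    config = cfg.default_config()
    entries = []
    for subj in subjects:
        slices = {}
        for st, ct in subj.slices.items():
            img_path = f"images/{subj.subject_id}_{st}.nii.gz"
            io.write_slice(ct, out / img_path)
            mask_paths = {}
            for name, mask in subj.truth_masks[st].masks.items():
                p = f"masks/{subj.subject_id}_{st}_{name}.nii.gz"
                io.write_mask(mask, ct.spacing_mm, out / p)
                mask_paths[name] = p
            slices[st] = {"image": img_path, "masks": mask_paths}
        entries.append(
            dict(subject_id=subj.subject_id, sex=subj.sex, cohort="PHANTOM",
                 slices=slices)
        )
    manifest = {
        "config_hash": cfg.config_hash(config),
        "seed": seed,
        "grid_size": grid_size,
        "entries": entries,
        "template_ids": {},
        "measurements": "measurements.csv",
    }
    io.write_manifest(manifest, out / "manifest.json")
    return manifest


def _load_manifest(run_dir) -> dict:
    return io.validate_manifest(Path(run_dir) / "manifest.json")


def stage_preprocess(run_dir) -> dict:
    """Standardize every slice and derive the classical masks; update manifest."""
    run = Path(run_dir)
    manifest = _load_manifest(run)
    (run / "proc").mkdir(exist_ok=True)
    for entry in manifest["entries"]:
        sid, sex = entry["subject_id"], entry["sex"]
        for st, files in entry["slices"].items():
            ct = io.read_slice(run / files["image"], st, sid, sex)
            truth = MaskSet({k: io.read_mask(run / p) for k, p in files["masks"].items()})
            std, masks, _ = preprocess.preprocess_subject(
                ct, _external_masks(truth, st), target_grid=manifest["grid_size"]
            )
            proc_path = f"proc/{sid}_{st}.nii.gz"
            io.write_slice(std, run / proc_path)
            files["proc"] = proc_path
            for name, mask in masks.masks.items():
                p = f"masks/{sid}_{st}_{name}.nii.gz"
                io.write_mask(mask, std.spacing_mm, run / p)
                files["masks"][name] = p
            if std.flags:
                files["flags"] = sorted(std.flags)
    io.write_manifest(manifest, run / "manifest.json")
    return manifest


def stage_select_templates(run_dir) -> dict:
    run = Path(run_dir)
    manifest = _load_manifest(run)
    meas = io.read_measurements(run / manifest["measurements"])
    slice_types = sorted({st for e in manifest["entries"] for st in e["slices"]})
    for st in slice_types:
        manifest["template_ids"][st] = {}
        for sex in ("M", "F"):
            tid = imiomics.select_template(meas, st, {"sex": sex})
            manifest["template_ids"][st][f"PHANTOM:{sex}"] = tid
    io.write_manifest(manifest, run / "manifest.json")
    return manifest


def _load_proc(run, entry, st):
    sid, sex = entry["subject_id"], entry["sex"]
    files = entry["slices"][st]
    std = io.read_slice(run / files["proc"], st, sid, sex)
    masks = MaskSet({k: io.read_mask(run / p) for k, p in files["masks"].items()})
    classmap = preprocess.tissue_class_map(std, masks["body"])
    return std, masks, classmap


def stage_register(run_dir, params: RegistrationParams | None = None) -> dict:
    """Register every subject to its group template, forward and reverse."""
    run = Path(run_dir)
    manifest = _load_manifest(run)
    params = params or RegistrationParams()
    (run / "fields").mkdir(exist_ok=True)
    by_id = {e["subject_id"]: e for e in manifest["entries"]}
    for st, groups in manifest["template_ids"].items():
        for gkey, tid in groups.items():
            sex = gkey.split(":")[-1]
            t_std, t_masks, t_classmap = _load_proc(run, by_id[tid], st)
            t_chan = preprocess.assemble_channels(t_std, t_masks)
            for entry in manifest["entries"]:
                if entry["sex"] != sex or entry["subject_id"] == tid:
                    continue
                if st not in entry["slices"]:
                    continue
                sid = entry["subject_id"]
                s_std, s_masks, s_classmap = _load_proc(run, entry, st)
                s_chan = preprocess.assemble_channels(s_std, s_masks)
                t0 = time.perf_counter()
                fwd = register_pair(t_chan, s_chan, t_classmap, params)
                rev = register_pair(s_chan, t_chan, s_classmap, params)
                dt = time.perf_counter() - t0
                fwd_p = f"fields/{sid}_{st}_fwd.nii.gz"
                rev_p = f"fields/{sid}_{st}_rev.nii.gz"
                io.write_field(fwd.field, run / fwd_p)
                io.write_field(rev.field, run / rev_p)
                entry["slices"][st]["field_fwd"] = fwd_p
                entry["slices"][st]["field_rev"] = rev_p
                entry["slices"][st]["registration_s"] = round(dt, 3)
                log.info("registered %s %s in %.2fs", sid, st, dt)
    io.write_manifest(manifest, run / "manifest.json")
    return manifest


def stage_evaluate(run_dir) -> pd.DataFrame:
    """Inverse-consistency report, one CSV row per registered pair."""
    run = Path(run_dir)
    manifest = _load_manifest(run)
    by_id = {e["subject_id"]: e for e in manifest["entries"]}
    rows = []
    for st, groups in manifest["template_ids"].items():
        for gkey, tid in groups.items():
            sex = gkey.split(":")[-1]
            t_std, t_masks, _ = _load_proc(run, by_id[tid], st)
            omega_t = _omega_from_body(t_masks["body"])
            for entry in manifest["entries"]:
                files = entry["slices"].get(st, {})
                if entry["sex"] != sex or "field_fwd" not in files:
                    continue
                sid = entry["subject_id"]
                if "field_rev" not in files:
                    raise ValueError(
                        f"{sid}/{st}: missing reverse-direction field "
                        "(forward field present; inverse consistency needs both)"
                    )
                s_std, s_masks, _ = _load_proc(run, entry, st)
                fwd = io.read_field(run / files["field_fwd"])
                rev = io.read_field(run / files["field_rev"])
                rep = transform_eval.pair_consistency(
                    fwd, rev, t_std, s_std, omega_t,
                    _omega_from_body(s_masks["body"]),
                    runtime_s=files.get("registration_s", float("nan")),
                )
                rows.append(
                    dict(cohort=entry["cohort"], slice=st, sex=sex, subject=sid,
                         vme_mm=rep.vme_mm, ime_hu=rep.ime_hu,
                         n_folds=rep.n_folds, runtime_s=rep.runtime_s)
                )
    evals = pd.DataFrame(rows, columns=EVAL_COLUMNS)
    evals.to_csv(run / "eval.csv", index=False)
    return evals


def stage_imiomics(run_dir, out_subdir: str = "imiomics") -> dict:
    """Build registered stacks and write beta/R² maps + the correlation matrix."""
    run = Path(run_dir)
    manifest = _load_manifest(run)
    meas = io.read_measurements(run / manifest["measurements"])
    out = run / out_subdir
    out.mkdir(exist_ok=True)
    by_id = {e["subject_id"]: e for e in manifest["entries"]}
    results = {}
    for st, groups in manifest["template_ids"].items():
        for gkey, tid in groups.items():
            sex = gkey.split(":")[-1]
            t_std, t_masks, _ = _load_proc(run, by_id[tid], st)
            omega_t = _omega_from_body(t_masks["body"])
            spacing2 = (t_std.spacing_mm[0] * 2, t_std.spacing_mm[1] * 2)
            hu_stack = [downsample(t_std.pixels, 1)]
            lj_stack = [np.zeros(omega_t.shape)]
            sids = [tid]
            for entry in manifest["entries"]:
                files = entry["slices"].get(st, {})
                if entry["sex"] != sex or "field_fwd" not in files:
                    continue
                sid = entry["subject_id"]
                s_std, _, _ = _load_proc(run, entry, st)
                fwd = io.read_field(run / files["field_fwd"])
                hu_stack.append(
                    resample_via_field(
                        s_std.pixels, s_std.spacing_mm, fwd,
                        background=float(s_std.pixels.min()),
                    )
                )
                lj_stack.append(transform_eval.jacobian_determinant(fwd).log_det)
                sids.append(sid)
            if len(sids) < 3:
                log.info("group %s/%s: %d subjects, regression refused", st, gkey, len(sids))
                continue
            rows = meas.set_index("subject_id").loc[sids].reset_index()
            maps = imiomics.run_group_regressions(
                np.stack(hu_stack), np.stack(lj_stack), rows, st, omega_t
            )
            results[(st, gkey)] = maps
            tag = gkey.replace(":", "_")
            for col, pair in maps.items():
                for resp, bm in pair.items():
                    for name, arr in (("beta0", bm.beta0), ("beta1", bm.beta1), ("r2", bm.r2)):
                        path = out / f"{st}_{tag}_{col}_{resp}_{name}.nii.gz"
                        _write_map(arr, spacing2, path)
    corr = imiomics.correlation_matrix(meas, _populated_columns(meas))
    corr.to_csv(out / "correlations.csv")
    return results


def _populated_columns(meas: pd.DataFrame) -> list[str]:
    """Measurement/covariate columns actually present for this cohort."""
    return [
        c for c in cfg.MEASUREMENT_COLUMNS + cfg.COVARIATE_COLUMNS
        if c in meas.columns and meas[c].notna().any()
    ]


def _write_map(arr: np.ndarray, spacing_mm, path) -> None:
    import nibabel as nib

    affine = np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))
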