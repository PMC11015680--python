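"""Template selection and voxel-wise statistics over registered cohorts.

The template (reference space) for each group is the subject closest to
the group "mean" in measurement space: the one minimizing the summed
absolute z-scores of the station's tissue-area measurements.

The voxel-wise analysis is mass-univariate simple linear regression: for
every voxel, the per-subject response (deformed HU, or log Jacobian
determinant as the local tissue-volume proxy) is regressed on one explicit
scalar measurement x,

    y_s = beta0 + beta1 * x_s + eps_s,   eps ~ N(0, sigma^2),

fit independently per voxel by ordinary least squares.  Slopes carry units
of HU/cm² (or log-Jac/cm²) for area measurements.  No spatial smoothing or
multiple-testing correction is applied; the outputs are the beta and R²
maps themselves.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import config as cfg
from .types import BetaMap

log = logging.getLogger(__name__)


def select_template(
    meas: pd.DataFrame,
    slice_type: str,
    group: dict | None = None,
    columns: list[str] | None = None,
) -> str:
    """Subject minimizing the summed |z| of the station's measurement columns.

    ``group`` filters rows (e.g. ``{"cohort": "SCAPIS", "sex": "M"}``);
    z-scores use the group sample SD (n-1).  Zero-SD columns are skipped
    with a warning; score ties break to the lexicographically smaller
    subject id.
    """
    df = meas
    for key, val in (group or {}).items():
        df = df[df[key] == val]
    if len(df) < 3:
        raise ValueError(f"need >= 3 subjects in group, got {len(df)}")
    columns = columns or cfg.TEMPLATE_COLUMNS[slice_type]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"measurement columns missing: {missing}")

    score = np.zeros(len(df))
    for col in columns:
        vals = df[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"column {col!r} has zero variance in group; skipped")
            continue
        score += np.abs((vals - vals.mean()) / sd)

    ids = df["subject_id"].to_numpy()
    best = score.min()
    winners = sorted(ids[score == best])
    log.info("template for %s %s: %s (sum|z| = %.4f)", slice_type, group, winners[0], best)
    return winners[0]


def voxelwise_regression(
    stack: np.ndarray,
    x: np.ndarray,
    omega: np.ndarray | None = None,
    covariate: str = "",
) -> BetaMap:
    """Independent per-voxel OLS of the subject stack on a scalar covariate.

    ``stack`` is (n, H, W) with one aligned map per subject.  Voxels where
    the response has zero variance get beta1 = 0 and R² defined as 0;
    voxels outside ``omega`` are NaN.
    """
    stack = np.asarray(stack, dtype=float)
    x = np.asarray(x, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != x.shape[0]:
        raise ValueError("stack must be (n, H, W) matching len(x)")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need n >= 3 subjects, got {n}")
    var_x = x.var()
    if var_x == 0:
        raise ValueError("covariate has zero variance")

    xc = x - x.mean()
    y_mean = stack.mean(axis=0)
    cov_xy = np.einsum("s,sij->ij", xc, stack) / n
    beta1 = cov_xy / var_x
    beta0 = y_mean - beta1 * x.mean()
    var_y = stack.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var_y > 0, cov_xy**2 / (var_x * var_y), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    if omega is not None:
        outside = ~np.asarray(omega, dtype=bool)
        for arr in (beta0, beta1, r2):
            arr[outside] = np.nan
    return BetaMap(beta0=beta0, beta1=beta1, r2=r2, n=n, covariate=covariate)


def correlation_matrix(meas: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Pearson correlation of the non-imaging columns (diagonal = 1).

    Zero-variance columns get NaN off-diagonal entries with a warning.
    Rows with missing values in the requested columns are dropped (logged).
    """
    df = meas[columns].astype(float)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        log.info("correlation_matrix: dropped %d incomplete rows", n_before - len(df))
    if len(df) < 3:
        raise ValueError("need >= 3 complete rows")

    vals = df.to_numpy()
    sd = vals.std(axis=0, ddof=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"zero-variance columns: {[c for c, b in zip(columns, bad) if b]}")
    centered = vals - vals.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / sd
    r = z.T @ z / len(df)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=columns, columns=columns)


# Default response-vs-measurement pairings per station, mirroring the
# proof-of-concept analyses (area driving the local intensity/size signal).
DEFAULT_REGRESSION_COLUMNS = {
    "liver": ["liver"],
    "abdomen": ["abdominal_muscle"],
    "thigh": ["thigh_muscle"],
}


def run_group_regressions(
    hu_stack: np.ndarray,
    logjac_stack: np.ndarray,
    meas_rows: pd.DataFrame,
    slice_type: str,
    omega: np.ndarray | None = None,
    columns: list[str] | None = None,
) -> dict[str, dict[str, BetaMap]]:
    """Voxel-wise fits of both responses against each configured measurement.

    Returns ``{column: {"hu": BetaMap, "logjac": BetaMap}}``.  Groups with
    fewer than 3 subjects are refused by :func:`voxelwise_regression`.
    """
    columns = columns or DEFAULT_REGRESSION_COLUMNS[slice_type]
    out: dict[str, dict[str, BetaMap]] = {}
    for col in columns:
        x = meas_rows[col].to_numpy(dtype=float)
        out[col] = {
            "hu": voxelwise_regression(hu_stack, x, omega, covariate=col),
            "logjac": voxelwise_regression(logjac_stack, x, omega, covariate=col),
        }
    return out
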