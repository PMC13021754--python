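"""Tracer harmonization and control-anchored z-scoring.

Amyloid PET SUVR values are tracer-specific; the Centiloid scale is a
linear rescaling that anchors 0 at the young-control mean and 100 at a
typical Alzheimer's-disease burden, making florbetapir (FBP) and
florbetaben (FBB) measurements comparable.  Regional measures are then
residualized against a normative model of age and sex fitted on an
amyloid-negative, APOE-e4-negative, cognitively normal control group, and
expressed as z-scores in units of the control residual standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TracerCalibration",
    "DEFAULT_CALIBRATIONS",
    "ControlModel",
    "centiloid_from_suvr",
    "suvr_from_centiloid",
    "is_amyloid_positive",
    "select_controls",
    "fit_control_model",
    "zscore_records",
]

log = logging.getLogger(__name__)

#: covariate / metadata columns expected on record tables
META_COLUMNS = ("subject_id", "visit", "tracer", "age", "sex", "group",
                "apoe4", "summary_suvr")


@dataclass(frozen=True)
class TracerCalibration:
    """Linear SUVR -> Centiloid map and SUVR positivity threshold."""

    tracer: str
    slope: float        # Centiloid per SUVR unit
    intercept: float    # Centiloid at SUVR 0
    positivity_threshold: float  # whole-cerebellum-referenced summary SUVR

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


#: published conversion equations and positivity cut-points for the two
#: tracers (florbetapir and florbetaben, whole-cerebellum reference)
DEFAULT_CALIBRATIONS: dict[str, TracerCalibration] = {
    "FBP": TracerCalibration("FBP", 188.22, -189.16, 1.11),
    "FBB": TracerCalibration("FBB", 157.15, -151.87, 1.08),
}


def _calibration(tracer: str, calibrations) -> TracerCalibration:
    calibrations = calibrations or DEFAULT_CALIBRATIONS
    try:
        return calibrations[tracer]
    except KeyError:
        raise KeyError(f"unknown tracer {tracer!r}; known: {sorted(calibrations)}")


def centiloid_from_suvr(tracer: str, suvr, calibrations=None):
    """Convert SUVR to Centiloid with the tracer's linear equation.

    Vectorized over array input; exact affine map ``slope*suvr + intercept``.
    """
    cal = _calibration(tracer, calibrations)
    suvr = np.asarray(suvr, dtype=float)
    if not np.all(np.isfinite(suvr)):
        raise ValueError("SUVR values must be finite")
    out = cal.slope * suvr + cal.intercept
    return float(out) if out.ndim == 0 else out


def suvr_from_centiloid(tracer: str, centiloid, calibrations=None):
    """Exact inverse of :func:`centiloid_from_suvr`."""
    cal = _calibration(tracer, calibrations)
    centiloid = np.asarray(centiloid, dtype=float)
    out = (centiloid - cal.intercept) / cal.slope
    return float(out) if out.ndim == 0 else out


def is_amyloid_positive(tracer: str, summary_suvr: float, calibrations=None,
                        inclusive: bool = True) -> bool:
    """Amyloid positivity call on the cortical summary SUVR.

    The boundary convention is ``>= threshold`` by default (configurable).
    """
    cal = _calibration(tracer, calibrations)
    if inclusive:
        return bool(summary_suvr >= cal.positivity_threshold)
    return bool(summary_suvr > cal.positivity_threshold)


def select_controls(records: pd.DataFrame, calibrations=None) -> pd.DataFrame:
    """Normative control subset: cognitively normal, zero APOE e4 copies,
    and amyloid-negative on the tracer-specific summary-SUVR threshold.

    Records with missing diagnosis, APOE count, tracer, or summary SUVR are
    excluded with a logged warning (no imputation).
    """
    needed = ["group", "apoe4", "tracer", "summary_suvr"]
    missing = records[needed].isna().any(axis=1)
    if missing.any():
        log.warning("select_controls: excluding %d records with missing "
                    "covariates", int(missing.sum()))
    r = records.loc[~missing]
    neg = [
        not is_amyloid_positive(t, s, calibrations)
        for t, s in zip(r["tracer"], r["summary_suvr"])
    ]
    keep = (r["group"] == "CN") & (r["apoe4"] == 0) & np.asarray(neg)
    return r.loc[keep]


@dataclass
class ControlModel:
    """Per-region normative regression  value ~ intercept + b_age*age + b_sex*sex
    with the residual SD estimated on controls."""

    regions: tuple[str, ...]
    intercept: np.ndarray   # (K,)
    age_slope: np.ndarray   # (K,)
    sex_offset: np.ndarray  # (K,)
    residual_sd: np.ndarray  # (K,) control residual SD
    n_controls: int = 0

    def predict(self, age, sex) -> np.ndarray:
        """Normative regional values, shape (n, K)."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        sex = np.atleast_1d(np.asarray(sex, dtype=float))
        return (self.intercept[None, :]
                + np.outer(age, self.age_slope)
                + np.outer(sex, self.sex_offset))


def fit_control_model(
    controls: pd.DataFrame,
    regions: list[str],
    min_residual_sd: float = 1e-10,
) -> ControlModel:
    """Ordinary least squares of each regional measure on age and sex,
    fitted on controls only; stores the control residual SD per region.

    Raises if fewer than 3 controls are given, if the design is
    rank-deficient (e.g. constant age and sex), or if any region is
    residual-degenerate (SD below ``min_residual_sd``).
    """
    n = len(controls)
    if n < 3:
        raise ValueError("need at least 3 controls to fit the normative model")
    X = np.column_stack([
        np.ones(n),
        controls["age"].to_numpy(dtype=float),
        controls["sex"].to_numpy(dtype=float),
    ])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < 3): age/sex must vary "
            "among controls"
        )
    Y = controls[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=X.shape[1])
    degenerate = sd < min_residual_sd
    if degenerate.any():
        bad = [regions[i] for i in np.flatnonzero(degenerate)]
        raise ValueError(
            f"degenerate control residual SD (< {min_residual_sd:g}) in "
            f"regions {bad}; z-scores undefined"
        )
    return ControlModel(
        regions=tuple(regions),
        intercept=beta[0],
        age_slope=beta[1],
        sex_offset=beta[2],
        residual_sd=sd,
        n_controls=n,
    )


def zscore_records(records: pd.DataFrame, model: ControlModel) -> pd.DataFrame:
    """Control-anchored z-scores for every record (controls and patients).

    z = (measured - predicted(age, sex)) / control residual SD, per region.
    Returns a DataFrame indexed like ``records`` with one column per region.
    """
    if np.any(model.residual_sd <= 0):
        raise ValueError("control model has non-positive residual SD")
    pred = model.predict(records["age"].to_numpy(), records["sex"].to_numpy())
    obs = records[list(model.regions)].to_numpy(dtype=float)
    z = (obs - pred) / model.residual_sd[None, :]
    return pd.DataFrame(z, index=records.index, columns=list(model.regions))
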