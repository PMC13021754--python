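"""End-to-end pipeline: harmonize -> z-score -> model selection -> fit ->
MCMC -> assignment -> longitudinal stability.

Configuration is a plain dict (usually loaded from YAML); every artifact
is written with a provenance block carrying the config hash, the seed, and
the producing stage, and a run manifest lists the stages executed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .events import EventGrid
from .harmonization import (DEFAULT_CALIBRATIONS, TracerCalibration,
                            centiloid_from_suvr, fit_control_model,
                            select_controls, zscore_records)
from .model import cvic_select, fit_subtypes, mcmc_sample
from .subtyping import (apply_longitudinal, assign_cohort, build_pvd,
                        plot_pvd, stability_metrics, summarize_rates)
from .synthetic import (SyntheticTruth, generate_cohort, generate_followup,
                        random_valid_ordering)

__all__ = ["PipelineError", "default_config", "run_pipeline", "simulate_to_disk"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "amystage_out",
        "data": {"records_csv": None, "followup_csv": None},
        "calibrations": {
            t: {"slope": c.slope, "intercept": c.intercept,
                "positivity_threshold": c.positivity_threshold}
            for t, c in DEFAULT_CALIBRATIONS.items()
        },
        "model": {
            "thresholds": [1.0, 2.0, 3.0],
            "z_max": 5.0,
            "sd": 1.0,
            "n_restarts": 25,
            "mcmc_iter": 100_000,
            "n_folds": 10,
            "max_subtypes": 3,
            "n_subtypes": None,   # fixed C overrides CVIC selection
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        # the calibration table is a versioned constants block: an override
        # replaces it wholesale rather than inheriting missing tracers
        if k != "calibrations" and isinstance(v, dict) \
                and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _calibrations_from_config(cfg) -> dict[str, TracerCalibration]:
    return {
        t: TracerCalibration(t, c["slope"], c["intercept"],
                             c["positivity_threshold"])
        for t, c in cfg["calibrations"].items()
    }


@dataclass
class PipelineResult:
    manifest: dict
    model: object
    assignments: pd.DataFrame
    stability: dict | None


def simulate_to_disk(outdir, n_subjects=400, n_controls=150, n_subtypes=2,
                     n_biomarkers=10, noise_sd=1.0, seed=0,
                     followup=True) -> dict:
    """Generate a synthetic cohort and write it as pipeline-ready CSVs."""
    if n_subjects <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    grid = EventGrid(tuple(f"roi_{i + 1}" for i in range(n_biomarkers)))
    orderings = np.stack([random_valid_ordering(grid, rng)
                          for _ in range(n_subtypes)])
    truth = SyntheticTruth(
        grid=grid, subtype_orderings=orderings,
        subtype_fractions=np.full(n_subtypes, 1.0 / n_subtypes),
        noise_sd=noise_sd, seed=seed,
    )
    records, cohort_truth = generate_cohort(truth, n_subjects, n_controls)
    prov = {"stage": "simulate", "seed": seed}
    aio.write_table(records, outdir / "records.csv", prov)
    files = {"records_csv": str(outdir / "records.csv")}
    if followup:
        fu = generate_followup(records, cohort_truth)
        aio.write_table(fu, outdir / "followup.csv", prov)
        files["followup_csv"] = str(outdir / "followup.csv")
    aio.write_json(cohort_truth.to_json_dict(), outdir / "truth.json", prov)
    files["truth_json"] = str(outdir / "truth.json")
    return files


def run_pipeline(config: dict, records: pd.DataFrame | None = None,
                 followup: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the full analysis; any stage failure raises
    :class:`PipelineError` naming the stage."""
    cfg = _merge(default_config(), config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the analysis-relevant configuration (not where it is written)
    chash = aio.config_hash({k: v for k, v in cfg.items()
                             if k != "output_dir"})
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict = {"config_hash": chash, "seed": seed, "stages": []}
    t0 = time.time()

    def stage_done(name):
        manifest["stages"].append(name)
        log.info("stage %-12s done (%.1fs elapsed)", name, time.time() - t0)

    def prov(stage):
        return {"config_hash": chash, "seed": seed, "stage": stage}

    # ---- load ------------------------------------------------------------
    if records is None:
        path = cfg["data"].get("records_csv")
        if not path:
            raise PipelineError("load", "no_input", "no record table given")
        records = aio.read_table(path)
        manifest["input_hash"] = aio.config_hash(
            records.to_csv(index=False))
    fu_path = cfg["data"].get("followup_csv")
    if followup is None and fu_path:
        followup = aio.read_table(fu_path)
    stage_done("load")

    # ---- harmonize -------------------------------------------------------
    calibrations = _calibrations_from_config(cfg)
    missing = set(records["tracer"]) - set(calibrations)
    if missing:
        raise PipelineError("harmonize", "missing_calibration",
                            f"no calibration for tracer(s) {sorted(missing)}")
    roi_cols = [c for c in records.columns if c.startswith("roi")]
    if not roi_cols:
        raise PipelineError("harmonize", "no_roi_columns",
                            "no roi_* columns in the record table")

    def to_centiloid(df):
        out = df.copy()
        for t in calibrations:
            m = (df["tracer"] == t).to_numpy()
            if m.any():
                out.loc[m, roi_cols] = centiloid_from_suvr(
                    t, df.loc[m, roi_cols].to_numpy(float), calibrations)
        return out

    records_cl = to_centiloid(records)
    aio.write_table(records_cl, outdir / "records_centiloid.csv",
                    prov("harmonize"))
    stage_done("harmonize")

    # ---- control model + z-scoring --------------------------------------
    controls = select_controls(records_cl, calibrations)
    if len(controls) < 3:
        raise PipelineError("zscore", "too_few_controls",
                            f"only {len(controls)} controls found")
    control_model = fit_control_model(controls, roi_cols)
    zdf = zscore_records(records_cl, control_model)
    z = zdf.to_numpy()
    aio.write_table(pd.concat([records_cl[["subject_id", "visit"]], zdf],
                              axis=1),
                    outdir / "zscores.csv", prov("zscore"))
    stage_done("zscore")

    # ---- model selection + fit -------------------------------------------
    mc = cfg["model"]
    grid = EventGrid(tuple(roi_cols), tuple(mc["thresholds"]),
                     float(mc["z_max"]))
    if mc.get("n_subtypes"):
        chosen = int(mc["n_subtypes"])
        manifest["cvic"] = None
    else:
        sel = cvic_select(z, grid, int(mc["max_subtypes"]),
                          n_folds=int(mc["n_folds"]),
                          seed=int(rng.integers(2**31)), sd=mc["sd"],
                          n_restarts=int(mc["n_restarts"]))
        chosen = sel.chosen
        manifest["cvic"] = dict(zip(map(int, sel.n_subtypes),
                                    map(float, sel.cvic)))
        aio.write_json(manifest["cvic"], outdir / "cvic.json", prov("cvic"))
    stage_done("cvic")

    model = fit_subtypes(z, grid, chosen, seed=int(rng.integers(2**31)),
                         sd=mc["sd"], n_restarts=int(mc["n_restarts"]))
    model.to_json(outdir / "model.json")
    manifest["n_subtypes"] = chosen
    manifest["threshold_order_violations"] = model.threshold_order_violations()
    stage_done("fit")

    # ---- MCMC + PVD -------------------------------------------------------
    samples = mcmc_sample(z, model, n_iter=int(mc["mcmc_iter"]),
                          seed=int(rng.integers(2**31)))
    pvd = build_pvd(samples)
    aio.write_json({"frequencies": pvd.frequencies,
                    "event_names": pvd.event_names},
                   outdir / "pvd.json", prov("mcmc"))
    plot_pvd(pvd, grid, outdir / "pvd.png")
    manifest["mcmc_acceptance_rate"] = samples.acceptance_rate
    stage_done("mcmc")

    # ---- assignment -------------------------------------------------------
    assignments = assign_cohort(z, model, records_cl["subject_id"],
                                visit="baseline")
    aio.write_table(assignments, outdir / "assignments.csv", prov("assign"))
    stage_done("assign")

    # ---- longitudinal -----------------------------------------------------
    stability = None
    if followup is not None:
        fu_cl = to_centiloid(followup)
        fu_assign = apply_longitudinal(model, fu_cl, control_model,
                                       baseline_ids=records_cl["subject_id"])
        aio.write_table(fu_assign, outdir / "assignments_followup.csv",
                        prov("longitudinal"))
        stability = stability_metrics(assignments, fu_assign)
        aio.write_json(stability, outdir / "stability.json",
                       prov("longitudinal"))
        base_rates = records_cl.assign(
            whole_brain_cl=records_cl[roi_cols].mean(axis=1))
        fu_rates = fu_cl.assign(whole_brain_cl=fu_cl[roi_cols].mean(axis=1))
        rate_cols = ["whole_brain_cl"]
        if "adas13" in records_cl.columns:
            rate_cols.append("adas13")
        rates = summarize_rates(base_rates, fu_rates, rate_cols)
        aio.write_table(rates, outdir / "rates.csv", prov("longitudinal"))
        stage_done("longitudinal")

    manifest["runtime_s"] = time.time() - t0
    aio.write_json(manifest, outdir / "manifest.json", prov("manifest"))
    return PipelineResult(manifest, model, assignments, stability)
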