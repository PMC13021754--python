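"""Subject assignment, positional variance diagrams, and longitudinal
stability.

Given a fitted subtype model, each subject is assigned a maximum a
posteriori stage and — unless that stage is 0, in which case they carry no
subtype — a maximum a posteriori subtype, with the stage-marginalized
subtype probability reported.  MCMC ordering samples are summarized as
positional variance diagrams (PVDs): per subtype, the frequency with which
each event occupies each stage position across samples.  Follow-up scans
are pushed through the frozen baseline pipeline (same control model, same
ROI masks, same fitted model) and paired baseline/follow-up assignments
yield stability counts and annualized change rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .harmonization import ControlModel, zscore_records
from .model import McmcSamples, SubtypeModel, subject_log_posteriors

__all__ = [
    "AssignmentResult",
    "PVD",
    "assign",
    "assign_cohort",
    "build_pvd",
    "pvd_correlation",
    "apply_longitudinal",
    "stability_metrics",
    "summarize_rates",
    "plot_pvd",
]

log = logging.getLogger(__name__)

NO_SUBTYPE = -1  # sentinel for Stage-0 "no subtype" assignments


@dataclass
class AssignmentResult:
    subject_id: str
    visit: str
    ml_stage: int
    ml_subtype: int           # NO_SUBTYPE at stage 0
    subtype_probability: float  # max stage-marginalized subtype probability
    expected_stage: float
    posterior: np.ndarray | None = None  # optional (C, N+1) grid


def _assign_arrays(z: np.ndarray, model: SubtypeModel):
    _, post = subject_log_posteriors(z, model)       # (n, C, S)
    stage_marg = post.sum(axis=1)                     # (n, S)
    subtype_marg = post.sum(axis=2)                   # (n, C)
    ml_stage = np.argmax(stage_marg, axis=1)          # ties -> lowest index
    ml_subtype = np.argmax(subtype_marg, axis=1)
    prob = subtype_marg[np.arange(len(z)), ml_subtype]
    ml_subtype = np.where(ml_stage == 0, NO_SUBTYPE, ml_subtype)
    exp_stage = stage_marg @ np.arange(model.grid.n_stages)
    return ml_stage, ml_subtype, prob, exp_stage, post


def assign(z_vector: np.ndarray, model: SubtypeModel,
           subject_id: str = "", visit: str = "baseline",
           keep_posterior: bool = False) -> AssignmentResult:
    """MAP subtype and stage for one subject's z-vector.

    Stage 0 implies no subtype; posterior ties resolve to the lower index.
    """
    z = np.atleast_2d(np.asarray(z_vector, dtype=float))
    st, sub, prob, es, post = _assign_arrays(z, model)
    return AssignmentResult(
        subject_id=subject_id, visit=visit, ml_stage=int(st[0]),
        ml_subtype=int(sub[0]), subtype_probability=float(prob[0]),
        expected_stage=float(es[0]),
        posterior=post[0] if keep_posterior else None,
    )


def assign_cohort(z_matrix: np.ndarray, model: SubtypeModel,
                  subject_ids=None, visit: str = "baseline") -> pd.DataFrame:
    """Vectorized assignment table for a cohort z-matrix."""
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    st, sub, prob, es, _ = _assign_arrays(z, model)
    if subject_ids is None:
        subject_ids = [f"S{i:05d}" for i in range(len(z))]
    return pd.DataFrame({
        "subject_id": list(subject_ids),
        "visit": visit,
        "ml_stage": st.astype(int),
        "ml_subtype": sub.astype(int),
        "subtype_probability": prob,
        "expected_stage": es,
    })


# ---------------------------------------------------------------------------
# positional variance diagrams


@dataclass
class PVD:
    """Per-subtype event x stage-position frequency matrices."""

    frequencies: np.ndarray   # (C, N, N): event e at position p
    event_names: list[str]

    @property
    def n_subtypes(self) -> int:
        return self.frequencies.shape[0]


def build_pvd(samples: McmcSamples) -> PVD:
    """Positional frequencies of every event across MCMC ordering samples.

    Each sampled ordering places every event at exactly one position, so
    each event's row sums to 1.
    """
    if samples.n_samples < 1:
        raise ValueError("no post-burn-in samples")
    S, C, N = samples.orderings.shape
    freq = np.zeros((C, N, N))
    positions = np.arange(N)
    for c in range(C):
        ords = samples.orderings[:, c, :].astype(np.int64)   # (S, N)
        for p in positions:
            counts = np.bincount(ords[:, p], minlength=N)
            freq[c, :, p] = counts
    freq /= S
    names = [samples.grid.event_name(e) for e in range(N)]
    return PVD(freq, names)


def pvd_correlation(pvd_a: PVD, pvd_b: PVD,
                    subtype_a: int = 0, subtype_b: int = 0) -> tuple[float, float]:
    """Pearson correlation between two flattened positional-frequency
    matrices — the similarity of two progression patterns."""
    a = pvd_a.frequencies[subtype_a].ravel()
    b = pvd_b.frequencies[subtype_b].ravel()
    if a.shape != b.shape:
        raise ValueError("PVDs must share one event grid")
    if a.std() < 1e-15 or b.std() < 1e-15:
        raise ValueError("zero-variance PVD: correlation undefined")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def plot_pvd(pvd: PVD, grid, path=None, axes=None):
    """Render PVDs as heatmaps with one RGB channel per z-level
    (magenta z=1, green z=2, cyan z=3 by convention)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    C = pvd.n_subtypes
    K, N = grid.n_biomarkers, grid.n_events
    channels = {1.0: np.array([1.0, 0.0, 1.0]),   # magenta
                2.0: np.array([0.0, 1.0, 0.0]),   # green
                3.0: np.array([0.0, 1.0, 1.0])}   # cyan
    if axes is None:
        fig, axes = plt.subplots(1, C, figsize=(4 * C, 3), squeeze=False)
        axes = axes[0]
    else:
        fig = axes[0].figure
    for c in range(C):
        img = np.ones((K, N, 3))
        for e in range(N):
            b = grid.event_biomarker[e]
            t = grid.event_threshold[e]
            col = channels.get(float(t), np.array([0.3, 0.3, 0.3]))
            w = pvd.frequencies[c, e][None, :, None]  # (1, N, 1)
            img[b] = img[b] * (1 - w) + w * col[None, None, :]
        ax = axes[c]
        ax.imshow(img, aspect="auto", interpolation="nearest")
        ax.set_xlabel("stage position")
        ax.set_yticks(range(K))
        ax.set_yticklabels(grid.biomarkers, fontsize=6)
        ax.set_title(f"subtype {c + 1}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# longitudinal application and stability


def apply_longitudinal(
    baseline_model: SubtypeModel,
    followup_records: pd.DataFrame,
    control_model: ControlModel,
    baseline_ids=None,
) -> pd.DataFrame:
    """Assign follow-up scans through the frozen baseline pipeline.

    No component is refitted: the control model (with follow-up age in the
    normative prediction) and the fitted subtype model are reused as-is.
    Subjects absent at baseline still receive assignments but are flagged
    for exclusion from paired stability metrics.
    """
    z = zscore_records(followup_records, control_model).to_numpy()
    out = assign_cohort(z, baseline_model,
                        subject_ids=followup_records["subject_id"],
                        visit="followup")
    if baseline_ids is not None:
        known = set(baseline_ids)
        unpaired = ~out["subject_id"].isin(known)
        if unpaired.any():
            log.warning("apply_longitudinal: %d follow-up subjects absent at "
                        "baseline; excluded from paired metrics",
                        int(unpaired.sum()))
        out["paired"] = ~unpaired
    else:
        out["paired"] = True
    return out


def stability_metrics(baseline: pd.DataFrame, followup: pd.DataFrame) -> dict:
    """Counts and percentages of subtype/stage transitions between visits.

    "Maintained subtype" includes Stage 0 at both visits.  Percentages are
    over the paired subjects; unpaired subjects are counted separately.
    """
    b = baseline.set_index("subject_id")
    f = followup.set_index("subject_id")
    common = b.index.intersection(f.index)
    n_unpaired = len(b.index.symmetric_difference(f.index))
    b, f = b.loc[common], f.loc[common]
    n = len(common)
    if n == 0:
        raise ValueError("no paired subjects")

    bs, fs = b["ml_subtype"].to_numpy(), f["ml_subtype"].to_numpy()
    bk, fk = b["ml_stage"].to_numpy(), f["ml_stage"].to_numpy()

    maintained = bs == fs
    stage0_to_higher = (bk == 0) & (fk > 0)
    to_stage0_by_subtype = {
        int(c): int(np.sum((bs == c) & (fs == NO_SUBTYPE)))
        for c in sorted(set(bs[bs != NO_SUBTYPE]))
    }
    subtype_changed = (~maintained) & (bs != NO_SUBTYPE) & (fs != NO_SUBTYPE)

    def pct(x):
        return 100.0 * x / n

    report = {
        "n_paired": n,
        "n_unpaired": n_unpaired,
        "maintained_subtype": int(maintained.sum()),
        "maintained_subtype_pct": pct(maintained.sum()),
        "maintained_by_category": {
            ("stage0" if c == NO_SUBTYPE else f"subtype_{c}"):
                int(np.sum(maintained & (bs == c)))
            for c in sorted(set(bs))
        },
        "stage0_to_higher": int(stage0_to_higher.sum()),
        "stage0_to_higher_pct": pct(stage0_to_higher.sum()),
        "subtype_changed": int(subtype_changed.sum()),
        "subtype_changed_pct": pct(subtype_changed.sum()),
        "subtype_to_stage0": to_stage0_by_subtype,
        "stage_same": int(np.sum(bk == fk)),
        "stage_same_pct": pct(np.sum(bk == fk)),
        "stage_progressed": int(np.sum(fk > bk)),
        "stage_progressed_pct": pct(np.sum(fk > bk)),
        "stage_regressed": int(np.sum(fk < bk)),
        "stage_regressed_pct": pct(np.sum(fk < bk)),
    }
    return report


def summarize_rates(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    measures: list[str],
    interval_column: str = "years_from_baseline",
) -> pd.DataFrame:
    """Per-subject annualized change (follow-up - baseline) / years.

    Pairs with a zero or negative interval are rejected.  Intervals given
    in days should be divided by 365.25 by the caller; this function uses
    the interval column as years directly.
    """
    b = baseline.set_index("subject_id")
    f = followup.set_index("subject_id")
    common = b.index.intersection(f.index)
    b, f = b.loc[common], f.loc[common]
    interval = (f[interval_column] - b[interval_column]).to_numpy(dtype=float)
    if np.any(interval <= 0):
        raise ValueError("zero or negative follow-up interval")
    out = {"subject_id": list(common), "interval_years": interval}
    for m in measures:
        out[f"{m}_rate"] = (f[m].to_numpy(float) - b[m].to_numpy(float)) / interval
    return pd.DataFrame(out)
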