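"""Ground-truth synthetic cohorts for the subtype-and-stage pipeline.

The generator is the model run forwards: each progressor carries a latent
subtype (an event ordering) and an integer stage; their regional z-values
follow the subtype's piecewise-linear trajectories plus Gaussian noise.
Controls sit at stage 0 and vary only through the normative age/sex model
and measurement noise.  Regional values are mapped from the z-scale to
Centiloid through a per-region control scale, and to tracer-specific SUVR
through the inverse Centiloid equations, so the harmonization stage of the
pipeline can round-trip them exactly.

Voxel-level volumes (for the spatial-ICA stage) are sums of nonnegative
spatial component maps weighted per subject so that the mean over each
component's support reproduces the subject's regional Centiloid value.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventGrid, trajectory_matrix
from .harmonization import ControlModel, centiloid_from_suvr, suvr_from_centiloid

__all__ = [
    "SyntheticTruth",
    "CohortTruth",
    "SyntheticVolumeSpec",
    "generate_cohort",
    "generate_followup",
    "generate_volumes",
    "make_blob_spec",
    "sample_z_cohort",
    "random_valid_ordering",
    "reverse_ordering",
]


def _sort_within_biomarker(grid: EventGrid, positions: np.ndarray) -> np.ndarray:
    """Reorder each biomarker's event positions so lower thresholds come
    first, preserving the set of positions."""
    pos = positions.copy()
    for i in range(grid.n_biomarkers):
        sel = np.flatnonzero(grid.event_biomarker == i)
        sel = sel[np.argsort(grid.event_threshold[sel])]
        pos[sel] = np.sort(pos[sel])
    return pos


def random_valid_ordering(grid: EventGrid, rng) -> np.ndarray:
    """Random event ordering in which every biomarker crosses its lower
    z-thresholds before its higher ones — the only orderings the forward
    (generative) model treats as monotone progressions."""
    rng = np.random.default_rng(rng)
    o = rng.permutation(grid.n_events)
    pos = np.empty(grid.n_events)
    pos[o] = np.arange(grid.n_events)
    return np.argsort(_sort_within_biomarker(grid, pos))


def reverse_ordering(grid: EventGrid, ordering: np.ndarray) -> np.ndarray:
    """Reverse a progression pattern: the last-affected regions become the
    first, while each biomarker still crosses its thresholds in increasing
    order (so the result is again a valid generative ordering)."""
    rev = np.asarray(ordering)[::-1]
    pos = np.empty(grid.n_events)
    pos[rev] = np.arange(grid.n_events)
    return np.argsort(_sort_within_biomarker(grid, pos))


@dataclass
class SyntheticTruth:
    """Generative parameters: the mirror image of the fitted model.

    ``noise_sd`` is measurement noise on the z-scale; the default of 1
    makes the control scatter equal one control SD, so downstream
    z-scoring is self-consistent.  ``control_scale`` converts z-units to
    Centiloid per region.
    """

    grid: EventGrid
    subtype_orderings: np.ndarray          # (C, N) permutations of events
    subtype_fractions: np.ndarray          # (C,) simplex
    noise_sd: float | np.ndarray = 1.0     # z-scale measurement noise
    control_scale: float | np.ndarray = 8.0  # Centiloid per control SD
    age_slope: float | np.ndarray = 0.3    # Centiloid per year, per region
    sex_offset: float | np.ndarray = 2.0   # Centiloid offset for sex=1
    baseline_centiloid: float | np.ndarray = 0.0  # region mean at age 72, sex 0
    age_mean: float = 72.0
    age_sd: float = 8.0
    stage_distribution: str = "uniform"    # over 0..N
    tracers: tuple[str, ...] = ("FBP", "FBB")
    seed: int = 0

    def __post_init__(self):
        self.subtype_orderings = np.atleast_2d(
            np.asarray(self.subtype_orderings, dtype=np.int64)
        )
        if self.subtype_orderings.shape[1] != self.grid.n_events:
            raise ValueError(
                "ordering length must equal the event count of the grid"
            )
        for row in self.subtype_orderings:
            self.grid.validate_ordering(row)
        self.subtype_fractions = np.asarray(self.subtype_fractions, dtype=float)
        if self.subtype_fractions.shape != (self.subtype_orderings.shape[0],):
            raise ValueError("one fraction per subtype required")
        if abs(self.subtype_fractions.sum() - 1.0) > 1e-12:
            raise ValueError("subtype fractions must sum to 1")
        K = self.grid.n_biomarkers
        for name in ("noise_sd", "control_scale", "age_slope", "sex_offset",
                     "baseline_centiloid"):
            setattr(self, name,
                    np.broadcast_to(np.asarray(getattr(self, name), float),
                                    (K,)).copy())
        if np.any(self.control_scale <= 0):
            raise ValueError("control_scale must be positive")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_subtypes(self) -> int:
        return self.subtype_orderings.shape[0]

    def baseline(self, age, sex) -> np.ndarray:
        """Normative regional Centiloid, shape (n, K); age centred at the
        cohort mean so the baseline level is interpretable directly."""
        age = np.atleast_1d(np.asarray(age, float))
        sex = np.atleast_1d(np.asarray(sex, float))
        return (self.baseline_centiloid[None, :]
                + np.outer(age - self.age_mean, self.age_slope)
                + np.outer(sex, self.sex_offset))

    def exact_control_model(self) -> ControlModel:
        """The true normative model (for noiseless round-trip checks the
        fitted one cannot provide)."""
        return ControlModel(
            regions=tuple(self.grid.biomarkers),
            intercept=self.baseline_centiloid - self.age_mean * self.age_slope,
            age_slope=self.age_slope.copy(),
            sex_offset=self.sex_offset.copy(),
            residual_sd=self.control_scale.copy(),
            n_controls=0,
        )


@dataclass
class CohortTruth:
    """Per-subject latent ground truth returned beside the record table."""

    params: SyntheticTruth
    table: pd.DataFrame       # subject_id, true_stage, true_subtype, latent_subtype
    z_true: np.ndarray        # (n, K) noise-free z-values g(stage)

    def to_json_dict(self) -> dict:
        return {
            "subtype_orderings": [
                [self.params.grid.event_name(e) for e in row]
                for row in self.params.subtype_orderings
            ],
            "subtype_fractions": self.params.subtype_fractions.tolist(),
            "noise_sd": self.params.noise_sd.tolist(),
            "seed": self.params.seed,
            "subjects": self.table.to_dict(orient="records"),
        }


def _sample_stages(rng, n, n_stages, law: str) -> np.ndarray:
    if law == "uniform":
        return rng.integers(0, n_stages, size=n)
    raise ValueError(f"unknown stage distribution {law!r}")


def generate_cohort(
    truth: SyntheticTruth, n_subjects: int, n_controls: int
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a baseline cohort of ``n_subjects`` progressors plus
    ``n_controls`` amyloid-negative controls.

    Progressor regional values are
    ``baseline(age, sex) + control_scale * (g(stage) + noise)`` in
    Centiloid, mapped to SUVR by the inverse tracer equation; controls are
    the same with g = 0 at stage 0.  Fully reproducible from ``truth.seed``.
    """
    if n_subjects <= 0 or n_controls <= 0:
        raise ValueError("n_subjects and n_controls must be positive")
    rng = np.random.default_rng(truth.seed)
    grid = truth.grid
    K, N = grid.n_biomarkers, grid.n_events
    n = n_subjects + n_controls
    is_control = np.zeros(n, dtype=bool)
    is_control[n_subjects:] = True

    age = rng.normal(truth.age_mean, truth.age_sd, n)
    sex = rng.integers(0, 2, n)
    tracer = rng.choice(truth.tracers, n)

    latent_subtype = rng.choice(truth.n_subtypes, n, p=truth.subtype_fractions)
    stage = _sample_stages(rng, n, N + 1, truth.stage_distribution)
    stage[is_control] = 0
    latent_subtype[is_control] = -1

    trajs = np.stack([trajectory_matrix(grid, s) for s in truth.subtype_orderings])
    z_true = np.zeros((n, K))
    prog = ~is_control
    z_true[prog] = trajs[latent_subtype[prog], :, stage[prog]]

    noise = rng.normal(0.0, 1.0, (n, K)) * truth.noise_sd[None, :]
    centiloid = truth.baseline(age, sex) + (z_true + noise) * truth.control_scale
    suvr = np.empty_like(centiloid)
    for t in truth.tracers:
        m = tracer == t
        suvr[m] = suvr_from_centiloid(t, centiloid[m])
    summary_suvr = suvr.mean(axis=1)

    group = np.where(is_control, "CN",
                     np.where(stage <= N // 3, rng.choice(["CN", "MCI"], n),
                              rng.choice(["MCI", "AD"], n)))
    apoe4 = np.where(is_control, 0, rng.choice([0, 1, 2], n, p=[0.5, 0.4, 0.1]))
    adas13 = 10.0 + 0.5 * stage + rng.normal(0.0, 2.0, n)

    records = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "visit": "baseline",
        "years_from_baseline": 0.0,
        "tracer": tracer,
        "age": age,
        "sex": sex,
        "group": group,
        "apoe4": apoe4,
        "adas13": adas13,
        "summary_suvr": summary_suvr,
        **{grid.biomarkers[i]: suvr[:, i] for i in range(K)},
    })
    true_subtype = np.where(stage == 0, -1, latent_subtype)
    truth_table = pd.DataFrame({
        "subject_id": records["subject_id"],
        "is_control": is_control,
        "true_stage": stage,
        "true_subtype": true_subtype,
        "latent_subtype": latent_subtype,
    })
    return records, CohortTruth(truth, truth_table, z_true)


def generate_followup(
    cohort: pd.DataFrame,
    truth: CohortTruth,
    mean_stage_increment: float = 2.0,
    mean_interval_years: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-sample every subject at stage + a Poisson increment (capped at N).

    Subjects keep their latent subtype; controls (no latent ordering to
    progress along) stay at stage 0.  A fresh noise draw is taken and the
    visit label distinguishes baseline from follow-up.
    """
    if mean_stage_increment < 0:
        raise ValueError("mean_stage_increment must be nonnegative")
    params = truth.params
    grid = params.grid
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    t = truth.table
    n, K, N = len(t), grid.n_biomarkers, grid.n_events

    increment = rng.poisson(mean_stage_increment, n)
    increment[t["is_control"].to_numpy()] = 0
    new_stage = np.minimum(t["true_stage"].to_numpy() + increment, N)
    interval = mean_interval_years * np.ones(n)

    trajs = np.stack(
        [trajectory_matrix(grid, s) for s in params.subtype_orderings]
    )
    lat = t["latent_subtype"].to_numpy()
    z_true = np.zeros((n, K))
    prog = lat >= 0
    z_true[prog] = trajs[lat[prog], :, new_stage[prog]]

    fu = cohort.copy()
    fu["visit"] = "followup"
    fu["years_from_baseline"] = interval
    fu["age"] = cohort["age"].to_numpy() + interval
    noise = rng.normal(0.0, 1.0, (n, K)) * params.noise_sd[None, :]
    centiloid = (params.baseline(fu["age"], fu["sex"])
                 + (z_true + noise) * params.control_scale)
    suvr = np.empty_like(centiloid)
    for trc in params.tracers:
        m = (fu["tracer"] == trc).to_numpy()
        suvr[m] = suvr_from_centiloid(trc, centiloid[m])
    for i in range(K):
        fu[grid.biomarkers[i]] = suvr[:, i]
    fu["summary_suvr"] = suvr.mean(axis=1)
    fu["adas13"] = 10.0 + 0.5 * new_stage + rng.normal(0.0, 2.0, n)
    fu.attrs["true_stage"] = new_stage
    return fu


def sample_z_cohort(
    grid: EventGrid,
    orderings: np.ndarray,
    fractions: np.ndarray,
    n_subjects: int,
    noise_sd: float = 1.0,
    seed: int | None = None,
    stage_distribution: str = "uniform",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directly sample a z-score matrix from the progression model.

    Shortcut for model-level experiments that do not need the SUVR /
    covariate layer: returns ``(z, true_subtype, true_stage)`` with
    ``z = g(stage; ordering[subtype]) + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(seed)
    orderings = np.atleast_2d(np.asarray(orderings, dtype=np.int64))
    fractions = np.asarray(fractions, dtype=float)
    subtype = rng.choice(len(orderings), n_subjects, p=fractions)
    stage = _sample_stages(rng, n_subjects, grid.n_stages, stage_distribution)
    trajs = np.stack([trajectory_matrix(grid, s) for s in orderings])
    z = trajs[subtype, :, stage] + rng.normal(0.0, noise_sd,
                                              (n_subjects, grid.n_biomarkers))
    return z, subtype, stage


# ---------------------------------------------------------------------------
# voxel-level volumes


@dataclass
class SyntheticVolumeSpec:
    """Spatial layout for voxel-level simulation: K nonnegative component
    maps and GM/WM/CSF tissue probability fields on one 3D grid."""

    shape: tuple[int, int, int]
    component_maps: np.ndarray      # (K, *shape), nonnegative
    gm: np.ndarray                  # tissue probabilities in [0, 1]
    wm: np.ndarray
    csf: np.ndarray
    mask_level: float = 0.5         # true-mask threshold, fraction of max
    noise_sd: float = 0.0           # voxel noise, Centiloid units
    component_masks: np.ndarray = field(init=False)

    def __post_init__(self):
        self.component_maps = np.asarray(self.component_maps, dtype=float)
        if self.component_maps.shape[1:] != tuple(self.shape):
            raise ValueError("component maps must live on the stated grid")
        for name in ("gm", "wm", "csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} map grid mismatch")
            setattr(self, name, arr)
        if np.any(self.component_maps < 0):
            raise ValueError("component maps must be nonnegative")
        if np.any(self.gm + self.wm + self.csf > 1 + 1e-9):
            raise ValueError("tissue probabilities must sum to <= 1 per voxel")
        peaks = self.component_maps.reshape(len(self.component_maps), -1).max(1)
        if np.any(peaks <= 0):
            raise ValueError("each component map needs positive support")
        self.component_masks = (
            self.component_maps >= self.mask_level * peaks[:, None, None, None]
        )


def make_blob_spec(
    shape: tuple[int, int, int] = (24, 24, 24),
    n_components: int = 4,
    sigma: float = 2.0,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> SyntheticVolumeSpec:
    """Isotropic Gaussian blobs at well-separated centres, placed in
    gray-matter territory; the remaining voxels are split between WM and CSF.
    """
    rng = np.random.default_rng(seed)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"))
    lo = 2 * sigma
    # half-maximum radius is sigma*sqrt(2 ln 2) ~ 1.18 sigma, so a 3.5 sigma
    # separation keeps the true (half-max) masks disjoint
    centers = []
    tries = 0
    while len(centers) < n_components:
        c = rng.uniform(lo, np.asarray(shape) - lo)
        if all(np.linalg.norm(c - np.asarray(o)) > 3.5 * sigma for o in centers):
            centers.append(c)
        tries += 1
        if tries > 10_000:
            raise ValueError("cannot place that many separated blobs; "
                             "enlarge the grid or shrink sigma")
    maps = np.stack([
        np.exp(-np.sum((grid - np.asarray(c)[:, None, None, None]) ** 2, axis=0)
               / (2 * sigma**2))
        for c in centers
    ])
    # blob territory is solid gray matter; elsewhere mostly WM with some CSF
    support = maps.sum(axis=0)
    in_gm = support > 0.25 * support.max()
    gm = np.where(in_gm, 0.85, 0.05)
    wm = np.where(in_gm, 0.10, 0.60)
    csf = np.where(in_gm, 0.04, 0.30)
    return SyntheticVolumeSpec(tuple(shape), maps, gm, wm, csf,
                               noise_sd=noise_sd)


def generate_volumes(
    cohort: pd.DataFrame,
    spec: SyntheticVolumeSpec,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-subject 3D Centiloid volumes, shape (n, *spec.shape).

    Each volume is a weighted sum of the component maps plus spatially
    white noise; the weights solve a small linear system so that, at noise
    0, the mean over each component's true mask equals the subject's
    regional Centiloid value.
    """
    K = len(spec.component_maps)
    if truth is not None:
        names = list(truth.grid.biomarkers)
    else:
        names = [c for c in cohort.columns if c.startswith("roi")]
    if len(names) != K:
        raise ValueError("component count must equal the biomarker count")
    rng = np.random.default_rng(seed)
    # M[r, i] = mean of map i over true mask of component r
    flat_maps = spec.component_maps.reshape(K, -1)
    flat_masks = spec.component_masks.reshape(K, -1)
    M = np.stack([flat_maps[:, m].mean(axis=1) for m in flat_masks])
    centiloid = np.stack([
        centiloid_from_suvr(t, row)
        for t, row in zip(cohort["tracer"], cohort[names].to_numpy(float))
    ])
    weights = np.linalg.solve(M, centiloid.T).T           # (n, K)
    vols = weights @ flat_maps                             # (n, voxels)
    if spec.noise_sd > 0:
        vols = vols + rng.normal(0.0, spec.noise_sd, vols.shape)
    return vols.reshape(len(cohort), *spec.shape)
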