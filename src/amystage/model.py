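"""Z-score event-based subtype-and-stage progression model.

The model describes a cohort as a mixture of C *subtypes*, each a distinct
ordering of the N threshold-crossing events, with subjects placed at latent
integer stages 0..N under a uniform stage prior.  Given a subject's
control-anchored z-scores ``z`` (length K), the likelihood under subtype c
at stage k is a product of independent Gaussians centred on the piecewise
linear trajectories implied by the subtype's event ordering:

    L(z | S_c, k) = prod_i  N(z_i | g_i(k; S_c), sd_i)

and the subject marginal is

    L(z) = sum_c f_c * (1 / (N+1)) * sum_{k=0}^{N} L(z | S_c, k).

Fitting maximizes the total log marginal likelihood by greedy event
relocation over orderings (with random restarts), subtypes are grown
hierarchically by splitting the worst-fitting cluster, and ordering
uncertainty is quantified by Metropolis–Hastings MCMC.  The number of
subtypes is selected by a ten-fold cross-validation information criterion
(CVIC = -2 x total out-of-fold log-likelihood).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .events import (EventGrid, batch_trajectories,
                     stage_log_likelihood_matrix, trajectory_matrix)

__all__ = [
    "SubtypeModel",
    "McmcSamples",
    "CvicResult",
    "stage_likelihood",
    "subject_likelihood",
    "subject_log_posteriors",
    "fit_single_subtype",
    "fit_subtypes",
    "mcmc_sample",
    "cvic_select",
]

_EPS_MONOTONE = 1e-8  # numerical slack on the EM monotonicity assertion


# ---------------------------------------------------------------------------
# model container


@dataclass
class SubtypeModel:
    """C event orderings with mixture fractions and a likelihood scale."""

    grid: EventGrid
    orderings: np.ndarray          # (C, N) int, permutations of events
    fractions: np.ndarray          # (C,) simplex
    sd: np.ndarray                 # (K,) per-biomarker likelihood SD

    def __post_init__(self):
        self.orderings = np.atleast_2d(np.asarray(self.orderings, dtype=np.int64))
        for row in self.orderings:
            self.grid.validate_ordering(row)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.orderings.shape[0],):
            raise ValueError("one fraction per subtype required")
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must lie on the simplex")
        self.sd = np.broadcast_to(
            np.asarray(self.sd, dtype=float), (self.grid.n_biomarkers,)
        ).copy()
        if np.any(self.sd <= 0):
            raise ValueError("likelihood sd must be positive")

    @property
    def n_subtypes(self) -> int:
        return self.orderings.shape[0]

    def trajectories(self) -> np.ndarray:
        """(C, K, N+1) expected z per subtype, biomarker, integer stage."""
        return batch_trajectories(self.grid, self.orderings)

    def threshold_order_violations(self) -> list[tuple[int, str]]:
        """Diagnostics: orderings where a biomarker's higher z-threshold
        precedes a lower one (not hard-enforced during search)."""
        out = []
        for c, s in enumerate(self.orderings):
            pos = np.empty(len(s))
            pos[s] = np.arange(len(s))
            for i, name in enumerate(self.grid.biomarkers):
                sel = self.grid.event_biomarker == i
                p = pos[sel][np.argsort(self.grid.event_threshold[sel])]
                if np.any(np.diff(p) < 0):
                    out.append((c, name))
        return out

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.grid.biomarkers),
            "thresholds": list(self.grid.thresholds),
            "z_max": self.grid.z_max,
            "orderings": [
                [self.grid.event_name(e) for e in row] for row in self.orderings
            ],
            "orderings_idx": self.orderings.tolist(),
            "fractions": self.fractions.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        grid = EventGrid(
            tuple(d["biomarkers"]), tuple(d["thresholds"]), float(d["z_max"])
        )
        return cls(grid, np.array(d["orderings_idx"]), np.array(d["fractions"]),
                   np.array(d["sd"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# likelihood


def stage_likelihood(z_vector, grid: EventGrid, ordering, stage: int, sd) -> float:
    """Likelihood of one subject's z-vector at a single (ordering, stage)."""
    z = np.atleast_2d(np.asarray(z_vector, dtype=float))
    traj = trajectory_matrix(grid, ordering, np.array([float(stage)]))
    ll = stage_log_likelihood_matrix(z, traj, sd)
    return float(np.exp(ll[0, 0]))


def _stage_ll(z: np.ndarray, model: SubtypeModel) -> np.ndarray:
    """(C, n, N+1) stage log-likelihood grid for every subtype."""
    return stage_log_likelihood_matrix(z, model.trajectories(), model.sd)


def subject_log_posteriors(
    z_matrix: np.ndarray, model: SubtypeModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject log marginal likelihood and joint posterior grid.

    Returns
    -------
    log_marginal : (n,) log of  sum_c f_c (1/(N+1)) sum_k L(z|S_c,k).
    posterior : (n, C, N+1) normalized posterior over subtype x stage,
        under the uniform stage prior.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    S = model.grid.n_stages
    ll = _stage_ll(z, model)                         # (C, n, S)
    log_joint = (
        ll.transpose(1, 0, 2)
        + np.log(model.fractions)[None, :, None]
        - np.log(S)
    )                                                # (n, C, S)
    log_marg = logsumexp(log_joint, axis=(1, 2))
    post = np.exp(log_joint - log_marg[:, None, None])
    return log_marg, post


def subject_likelihood(z_vector, model: SubtypeModel) -> tuple[float, np.ndarray]:
    """Marginal likelihood and subtype x stage posterior for one subject."""
    lm, post = subject_log_posteriors(np.atleast_2d(z_vector), model)
    return float(np.exp(lm[0])), post[0]


def total_log_likelihood(z_matrix, model: SubtypeModel) -> float:
    lm, _ = subject_log_posteriors(z_matrix, model)
    return float(lm.sum())


# ---------------------------------------------------------------------------
# maximum-likelihood ordering search


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Minimal log-sum-exp (hot path; scipy's generality costs too much)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


try:  # single-pass log-sum-exp over the last axis; pure-numpy fallback
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _lse_last_axis_2d(a):  # (rows, S) -> (rows,)
        rows, S = a.shape
        out = np.empty(rows)
        for r in range(rows):
            m = a[r, 0]
            for s in range(1, S):
                if a[r, s] > m:
                    m = a[r, s]
            acc = 0.0
            for s in range(S):
                acc += np.exp(a[r, s] - m)
            out[r] = m + np.log(acc)
        return out
except ImportError:  # pragma: no cover
    def _lse_last_axis_2d(a):
        return _lse(a, axis=1)


def _log_stage_mean(z, grid, orderings, sd) -> np.ndarray:
    """log of the stage-averaged likelihood, batched over candidate
    orderings: (B, n) from orderings (B, N).

    Equivalent to ``logsumexp(stage_log_likelihood_matrix(...), axis=2)
    - log(S)`` but fused: the subject-constant quadratic term is pulled out
    of the log-sum-exp and the remaining grid is one BLAS product plus
    in-place exponentials.  This is the inner loop of every fit.
    """
    z = np.asarray(z, dtype=float)
    n, K = z.shape
    traj = batch_trajectories(grid, orderings)          # (B, K, S)
    B, _, S = traj.shape
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (K,))
    inv_var = 1.0 / sd**2
    const = 0.5 * K * np.log(2.0 * np.pi) + np.sum(np.log(sd))
    zz = np.sum(z**2 * inv_var, axis=1)                 # (n,)
    arg = (z * inv_var) @ traj.transpose(1, 0, 2).reshape(K, B * S)
    arg -= 0.5 * (traj**2 * inv_var[None, :, None]).sum(axis=1).reshape(B * S)
    lm = _lse_last_axis_2d(arg.reshape(n * B, S)).reshape(n, B)
    lm += (-0.5 * zz - const - np.log(S))[:, None]
    return np.ascontiguousarray(lm.T)                   # (B, n)


def _relocation_candidates(ordering: np.ndarray, event: int) -> np.ndarray:
    """All orderings obtained by moving one event to every position."""
    N = len(ordering)
    rest = ordering[ordering != event]
    out = np.empty((N, N), dtype=np.int64)
    for p in range(N):
        out[p, :p] = rest[:p]
        out[p, p] = event
        out[p, p + 1:] = rest[p:]
    return out


def _greedy_orderings(z, grid, ordering, sd, objective, max_sweeps=30):
    """Iterated single-event relocation until no strict improvement.

    ``objective`` maps the (B, n) log stage-mean matrix of candidate
    orderings to a (B,) total objective; ties break to the lowest candidate
    index, and the current ordering is kept unless a candidate is strictly
    better.
    """
    ordering = np.asarray(ordering, dtype=np.int64).copy()
    best = float(objective(_log_stage_mean(z, grid, ordering[None], sd))[0])
    for _ in range(max_sweeps):
        improved = False
        for event in range(grid.n_events):
            cands = _relocation_candidates(ordering, event)
            obj = objective(_log_stage_mean(z, grid, cands, sd))
            j = int(np.argmax(obj))
            if obj[j] > best + 1e-12:
                ordering = cands[j]
                best = float(obj[j])
                improved = True
        if not improved:
            break
    return ordering, best


def fit_single_subtype(
    z_matrix: np.ndarray,
    grid: EventGrid,
    n_restarts: int = 25,
    seed: int | None = None,
    sd: float | np.ndarray = 1.0,
    max_sweeps: int = 30,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood event ordering for a one-subtype model.

    Multiple random initial permutations are each refined by greedy event
    relocation; the best restart is returned.  Deterministic given ``seed``.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    if z.shape[0] < 2:
        raise ValueError("at least 2 subjects required")
    if z.shape[1] != grid.n_biomarkers:
        raise ValueError("z-matrix width must equal the number of biomarkers")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)

    def objective(log_means):  # (B, n) -> (B,)
        return log_means.sum(axis=1)

    best_ord, best_ll = None, -np.inf
    for _ in range(n_restarts):
        init = rng.permutation(grid.n_events)
        ordering, ll = _greedy_orderings(z, grid, init, sd, objective,
                                         max_sweeps=max_sweeps)
        if ll > best_ll:
            best_ord, best_ll = ordering, ll
    if best_ord is None or not np.isfinite(best_ll):
        raise RuntimeError("all restarts degenerate")
    return best_ord, best_ll


# ---------------------------------------------------------------------------
# hierarchical subtype fitting


def _mixture_objective(log_rest: np.ndarray, log_f: float):
    """Total mixture log-likelihood as a function of one subtype's
    candidate log stage-means, with the other subtypes' contribution
    per subject fixed at ``log_rest``."""

    def objective(log_means):  # (B, n)
        return np.logaddexp(log_rest[None, :], log_f + log_means).sum(axis=1)

    return objective


def _em_refine(z, grid, orderings, fractions, sd, rng, tol, max_iter,
               greedy_sweeps=3, history=None):
    """Alternate fraction EM updates and per-subtype coordinate-ascent
    ordering re-optimization; total log-likelihood is monotone and asserted
    so at every iteration."""
    C = len(orderings)
    model = SubtypeModel(grid, orderings, fractions, sd)
    prev = total_log_likelihood(z, model)
    if history is not None:
        history.append(prev)
    for _ in range(max_iter):
        # E-step responsibilities + M-step fraction update
        log_mc = _log_stage_mean(z, grid, model.orderings, model.sd)  # (C, n)
        log_wc = log_mc + np.log(model.fractions)[:, None]
        resp = np.exp(log_wc - logsumexp(log_wc, axis=0, keepdims=True))
        fractions = resp.mean(axis=1)
        if np.any(fractions < 1e-12):
            # empty subtype: re-seed once from the worst-fit subjects
            worst = np.argsort(logsumexp(log_wc, axis=0))[: max(2, len(z) // 10)]
            dead = int(np.argmin(fractions))
            reseed, _ = fit_single_subtype(z[worst], grid, 3, rng.integers(2**31),
                                           sd=model.sd)
            orderings = model.orderings.copy()
            orderings[dead] = reseed
            fractions = np.full(C, 1.0 / C)
            model = SubtypeModel(grid, orderings, fractions, sd)
            prev = total_log_likelihood(z, model)
            continue
        fractions = fractions / fractions.sum()
        model = SubtypeModel(grid, model.orderings, fractions, model.sd)
        # coordinate ascent on each subtype's ordering (total-likelihood
        # objective, so monotone by construction)
        orderings = model.orderings.copy()
        for c in range(C):
            others = [c2 for c2 in range(C) if c2 != c]
            if others:
                log_mo = _log_stage_mean(z, grid, orderings[others], model.sd)
                log_rest = logsumexp(
                    log_mo + np.log(model.fractions[others])[:, None], axis=0
                )
            else:
                log_rest = np.full(len(z), -np.inf)
            obj = _mixture_objective(log_rest, np.log(model.fractions[c]))
            orderings[c], _ = _greedy_orderings(
                z, grid, orderings[c], model.sd, obj, max_sweeps=greedy_sweeps
            )
        model = SubtypeModel(grid, orderings, model.fractions, model.sd)
        cur = total_log_likelihood(z, model)
        if cur < prev - _EPS_MONOTONE:
            raise AssertionError(
                f"log-likelihood decreased during EM: {prev} -> {cur}"
            )
        if history is not None:
            history.append(cur)
        if cur - prev < tol:
            prev = cur
            break
        prev = cur
    return model, prev


def _cem_split(z, grid, sd, rng, n_tries=3, max_iter=8, n_restarts=2):
    """Two-cluster split of a subject set by hard classification EM.

    The first try is seeded by k-means on direction-normalized z-vectors
    (progression *patterns*, discounting stage), which breaks the symmetry
    that defeats purely random bisections; the remaining tries start from
    random bisections.  Each try alternates (a) fitting the
    maximum-likelihood ordering within each cluster (warm-started greedy
    after the first round) and (b) reassigning every subject to the
    ordering that explains it better, until the partition is stable.  The
    try with the highest two-cluster mixture likelihood wins.
    """
    from sklearn.cluster import KMeans

    n = len(z)
    norms = np.linalg.norm(z, axis=1)
    zn = z / np.maximum(norms, 1e-9)[:, None]
    # cluster patterns on the informative (above-median burden) subjects
    # only — near-baseline directions are noise — then spread to everyone
    informative = norms > np.median(norms)
    if informative.sum() >= 4:
        km = KMeans(2, n_init=10, random_state=int(rng.integers(2**31)))
        km.fit(zn[informative])
        pattern_labels = km.predict(zn).astype(np.int64)
    else:
        pattern_labels = rng.integers(0, 2, n)
    inits = [pattern_labels]
    inits += [rng.integers(0, 2, n) for _ in range(max(0, n_tries - 1))]

    def score_of(ords, labels):
        f = np.bincount(labels, minlength=2) / n
        f = np.clip(f, 0.05, 0.95)
        f = f / f.sum()
        lm = _log_stage_mean(z, grid, np.stack(ords), sd)
        s = float(np.logaddexp(lm[0] + np.log(f[0]),
                               lm[1] + np.log(f[1])).sum())
        return s, f, lm

    best = None
    for labels in inits:
        labels = labels.copy()
        if labels.min() == labels.max():
            labels[: n // 2] = 1 - labels[0]
        ords: list[np.ndarray | None] = [None, None]
        for it in range(max_iter):
            sizes = np.bincount(labels, minlength=2)
            if sizes.min() < 2:
                break
            for c in (0, 1):
                zc = z[labels == c]
                if it == 0 or ords[c] is None:
                    ords[c], _ = fit_single_subtype(
                        zc, grid, n_restarts, int(rng.integers(2**31)), sd,
                        max_sweeps=4)
                else:
                    ords[c], _ = _greedy_orderings(
                        zc, grid, ords[c], sd, lambda lm: lm.sum(axis=1),
                        max_sweeps=2)
            # the hard reassignment can oscillate, so keep the best-scoring
            # state seen rather than the last
            score, f, lm = score_of(ords, labels)
            if best is None or score > best[0]:
                best = (score, np.stack(ords), f)
            new = np.argmax(lm, axis=0)
            if np.array_equal(new, labels):
                break
            labels = new
    if best is None:
        raise RuntimeError("two-cluster split failed: clusters degenerate")
    return best[1], best[2]


def fit_subtypes(
    z_matrix: np.ndarray,
    grid: EventGrid,
    n_subtypes: int,
    seed: int | None = None,
    sd: float | np.ndarray = 1.0,
    n_restarts: int = 25,
    tol: float = 1e-4,
    max_iter: int = 50,
    split_tries: int = 3,
    split_max_iter: int = 8,
    init_model: "SubtypeModel | None" = None,
    return_history: bool = False,
):
    """Hierarchical maximum-likelihood fit of a C-subtype model.

    The C-1 solution's worst-fitting cluster (largest summed squared
    residual around its ML trajectory) is split by a two-cluster hard-CEM
    initialization of its assigned subjects; the C orderings and fractions
    are then refined by alternating EM fraction updates and greedy ordering
    re-optimization until the log-likelihood gain falls below ``tol``.
    The total log-likelihood is non-decreasing across refinement iterations
    and asserted so.

    ``init_model`` (with fewer subtypes, fitted on the same data) lets the
    hierarchy continue from an earlier stage instead of refitting it.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    rng = np.random.default_rng(seed)
    history: list[float] | None = [] if return_history else None

    if init_model is not None:
        if init_model.n_subtypes > n_subtypes:
            raise ValueError("init_model must not have more subtypes than "
                             "requested")
        model = init_model
        if history is not None:
            history.append(total_log_likelihood(z, model))
    else:
        ordering, ll = fit_single_subtype(z, grid, n_restarts,
                                          rng.integers(2**31), sd)
        model = SubtypeModel(grid, ordering[None], np.array([1.0]), sd)
        if history is not None:
            history.append(ll)

    for C in range(model.n_subtypes + 1, n_subtypes + 1):
        # pick the cluster to split: largest total squared residual at the
        # subjects' ML (subtype, stage) cells
        _, post = subject_log_posteriors(z, model)
        flat = post.reshape(len(z), -1)
        cell = np.argmax(flat, axis=1)
        c_ml = cell // model.grid.n_stages
        k_ml = cell % model.grid.n_stages
        traj = model.trajectories()                  # (C-1, K, S)
        resid = z - traj[c_ml, :, k_ml]
        scores = np.zeros(model.n_subtypes)
        np.add.at(scores, c_ml, np.sum(resid**2, axis=1))
        split = int(np.argmax(scores))
        members = np.flatnonzero(c_ml == split)
        if len(members) < 8:
            members = np.arange(len(z))
        split_restarts = max(1, min(2, n_restarts // 2))
        pair, f_pair = _cem_split(z[members], grid, sd, rng,
                                  n_tries=split_tries,
                                  max_iter=split_max_iter,
                                  n_restarts=split_restarts)
        orderings = np.vstack([np.delete(model.orderings, split, axis=0), pair])
        f_old = np.delete(model.fractions, split)
        f_split = model.fractions[split]
        fractions = np.concatenate([f_old, f_split * f_pair])
        fractions = fractions / fractions.sum()
        model, _ = _em_refine(z, grid, orderings, fractions, sd, rng,
                              tol, max_iter, history=history)

    if return_history:
        return model, history
    return model


# ---------------------------------------------------------------------------
# MCMC over orderings and fractions


@dataclass
class McmcSamples:
    """Post burn-in posterior samples of (orderings, fractions)."""

    orderings: np.ndarray      # (S, C, N) int16
    fractions: np.ndarray      # (S, C)
    log_likelihoods: np.ndarray  # full trace, length n_iter
    n_iter: int
    burn_in: int
    seed: int | None
    acceptance_rate: float
    grid: EventGrid = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.orderings.shape[0]


def mcmc_sample(
    z_matrix: np.ndarray,
    model: SubtypeModel,
    n_iter: int = 100_000,
    seed: int | None = None,
    burn_in_fraction: float = 0.1,
    fraction_step: float = 0.02,
) -> McmcSamples:
    """Metropolis–Hastings over event orderings and mixture fractions.

    Ordering proposal: swap two random event positions within one random
    subtype.  Fraction proposal (C > 1): jointly perturb the fractions with
    symmetric Gaussian noise and renormalize (treated as symmetric).
    Acceptance is by total-likelihood ratio; the chain records the
    log-likelihood at every iteration and keeps post-burn-in states.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    burn_in = int(round(n_iter * burn_in_fraction))
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed the burn-in length")
    rng = np.random.default_rng(seed)
    grid, sd = model.grid, model.sd
    C, N = model.orderings.shape

    orderings = model.orderings.copy()
    fractions = model.fractions.copy()
    log_mc = _log_stage_mean(z, grid, orderings, sd)      # (C, n)

    def total_ll(log_mc_, f_):
        return float(
            logsumexp(log_mc_ + np.log(f_)[:, None], axis=0).sum()
        )

    cur_ll = total_ll(log_mc, fractions)
    trace = np.empty(n_iter)
    keep = n_iter - burn_in
    samp_ord = np.empty((keep, C, N), dtype=np.int16)
    samp_f = np.empty((keep, C))
    n_accept = 0

    for it in range(n_iter):
        move_fractions = C > 1 and rng.random() < 0.2
        if move_fractions:
            prop = np.abs(fractions + rng.normal(0.0, fraction_step, C))
            prop = np.maximum(prop, 1e-12)
            prop = prop / prop.sum()
            new_ll = total_ll(log_mc, prop)
            if np.log(rng.random()) < new_ll - cur_ll:
                fractions, cur_ll = prop, new_ll
                n_accept += 1
        else:
            c = int(rng.integers(C))
            i, j = rng.integers(N), rng.integers(N)
            prop_ord = orderings[c].copy()
            prop_ord[i], prop_ord[j] = prop_ord[j], prop_ord[i]
            new_row = _log_stage_mean(z, grid, prop_ord[None], sd)[0]
            log_mc_prop = log_mc.copy()
            log_mc_prop[c] = new_row
            new_ll = total_ll(log_mc_prop, fractions)
            if np.log(rng.random()) < new_ll - cur_ll:
                orderings = orderings.copy()
                orderings[c] = prop_ord
                log_mc, cur_ll = log_mc_prop, new_ll
                n_accept += 1
        trace[it] = cur_ll
        if it >= burn_in:
            samp_ord[it - burn_in] = orderings
            samp_f[it - burn_in] = fractions

    return McmcSamples(
        orderings=samp_ord,
        fractions=samp_f,
        log_likelihoods=trace,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        acceptance_rate=n_accept / n_iter,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class CvicResult:
    """Per-C cross-validation information criterion and the chosen C."""

    n_subtypes: np.ndarray     # candidate C values
    cvic: np.ndarray           # CVIC(C) = -2 * total out-of-fold loglik
    chosen: int                # argmin CVIC
    chosen_parsimonious: int   # smallest C within `margin` of the minimum
    margin: float
    fold_loglik: np.ndarray    # (len(C), n_folds) out-of-fold sums


def _posterior_averaged_oof(z_test, grid, sd, samples: McmcSamples,
                            n_eval_samples: int) -> float:
    """Out-of-fold log-likelihood averaged over MCMC posterior samples:
    sum_i log( (1/S) sum_s L(z_i | orderings_s, fractions_s) )."""
    S = samples.n_samples
    take = np.linspace(0, S - 1, min(n_eval_samples, S)).astype(int)
    per_sample = np.empty((len(take), len(z_test)))
    for j, s in enumerate(take):
        ords = samples.orderings[s].astype(np.int64)
        log_mc = _log_stage_mean(z_test, grid, ords, sd)        # (C, n)
        per_sample[j] = logsumexp(
            log_mc + np.log(samples.fractions[s])[:, None], axis=0)
    return float((logsumexp(per_sample, axis=0) - np.log(len(take))).sum())


def cvic_select(
    z_matrix: np.ndarray,
    grid: EventGrid,
    max_subtypes: int,
    n_folds: int = 10,
    seed: int | None = None,
    sd: float | np.ndarray = 1.0,
    n_restarts: int = 25,
    parsimony_margin: float = 6.0,
    mcmc_iter: int = 20_000,
    n_eval_samples: int = 50,
    **fit_kwargs,
) -> CvicResult:
    """Select the number of subtypes by ten-fold cross-validation.

    For each candidate C the model is fitted on 9/10 of the subjects, its
    posterior is sampled by MCMC, and the held-out log likelihood —
    averaged over the sampled models, so that every C enjoys the same
    hedging over ordering uncertainty — is accumulated;
    CVIC(C) = -2 x total out-of-fold log-likelihood is minimized.  With
    ``mcmc_iter=0`` the maximum-likelihood fit is used instead.  A
    parsimonious alternative (the smallest C whose CVIC is within
    ``parsimony_margin`` of the minimum) is also reported, mirroring the
    practice of preferring a smaller model when the improvement is marginal.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    n = len(z)
    if n < n_folds:
        raise ValueError("need at least one subject per fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    if any(len(f) == 0 for f in folds):
        raise ValueError("empty cross-validation fold")

    Cs = np.arange(1, max_subtypes + 1)
    fold_ll = np.zeros((len(Cs), n_folds))
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        prev = None
        for ci, C in enumerate(Cs):
            # grow the hierarchy across C within a fold instead of
            # refitting the lower-order stages from scratch
            m = fit_subtypes(z[train_mask], grid, int(C),
                             seed=rng.integers(2**31), sd=sd,
                             n_restarts=n_restarts, init_model=prev,
                             **fit_kwargs)
            prev = m
            if mcmc_iter > 0:
                samples = mcmc_sample(z[train_mask], m, n_iter=mcmc_iter,
                                      seed=int(rng.integers(2**31)))
                fold_ll[ci, fi] = _posterior_averaged_oof(
                    z[test_idx], grid, m.sd, samples, n_eval_samples)
            else:
                lm, _ = subject_log_posteriors(z[test_idx], m)
                fold_ll[ci, fi] = lm.sum()
    cvic = -2.0 * fold_ll.sum(axis=1)
    chosen = int(Cs[np.argmin(cvic)])
    within = cvic <= cvic.min() + parsimony_margin
    chosen_pars = int(Cs[np.argmax(within)])
    return CvicResult(Cs, cvic, chosen, chosen_pars, parsimony_margin, fold_ll)
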