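"""Event grid and z-score trajectory primitives.

An *event* is the crossing of a fixed z-threshold (by default 1, 2, or 3
control standard deviations) by one regional biomarker.  With K biomarkers
and three thresholds each there are N = 3K events, and a subject's *stage*
is the number of events that have already occurred (0..N).  A *subtype* is
a permutation of the N events — an ordering of threshold crossings.

The expected z-value of a biomarker at a given stage is piecewise linear:
0 at stage 0, equal to threshold ``z_j`` at the stage position of the event
``(biomarker, z_j)`` in the ordering, and rising to a plateau target
``z_max`` (default 5) at stage N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventGrid", "trajectory_value", "trajectory_matrix",
           "batch_trajectories"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EventGrid:
    """The biomarker x z-threshold event space defining stages 0..N.

    Parameters
    ----------
    biomarkers : list of str
        Names of the K regional biomarkers (e.g. ICA-derived ROI names).
    thresholds : tuple of float
        Strictly increasing z-levels whose crossings define events.
        Shared across biomarkers.
    z_max : float
        Plateau z-value reached by every biomarker at stage N.
    """

    biomarkers: tuple[str, ...]
    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    # flat event enumeration: event e = (biomarker_of[e], threshold_of[e])
    event_biomarker: np.ndarray = field(init=False, repr=False, compare=False)
    event_threshold: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "biomarkers", tuple(self.biomarkers))
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        if len(self.biomarkers) == 0:
            raise ValueError("at least one biomarker required")
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if t[-1] >= self.z_max:
            raise ValueError("all thresholds must lie below z_max")
        K, L = len(self.biomarkers), len(t)
        object.__setattr__(
            self, "event_biomarker", np.repeat(np.arange(K), L)
        )
        object.__setattr__(self, "event_threshold", np.tile(t, K))

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_events(self) -> int:
        """N, the total number of events; stages run 0..N."""
        return len(self.biomarkers) * len(self.thresholds)

    @property
    def n_stages(self) -> int:
        """Number of stage values (N + 1, including stage 0)."""
        return self.n_events + 1

    def event_name(self, e: int) -> str:
        return f"{self.biomarkers[self.event_biomarker[e]]}@z{self.event_threshold[e]:g}"

    def event_index(self, biomarker: int | str, threshold: float) -> int:
        if isinstance(biomarker, str):
            biomarker = self.biomarkers.index(biomarker)
        hits = np.flatnonzero(
            (self.event_biomarker == biomarker)
            & np.isclose(self.event_threshold, threshold)
        )
        if len(hits) != 1:
            raise KeyError(f"no event ({biomarker}, z={threshold})")
        return int(hits[0])

    def validate_ordering(self, ordering: np.ndarray) -> np.ndarray:
        ordering = np.asarray(ordering, dtype=np.int64)
        if sorted(ordering.tolist()) != list(range(self.n_events)):
            raise ValueError("ordering must be a permutation of all events")
        return ordering


try:  # fused fast path for the integer-stage grid (search inner loop)
    import numba as _numba

    @_numba.njit(cache=True)
    def _batch_traj_jit(position, thresholds, K, L, N, z_max):
        B = position.shape[0]
        out = np.empty((B, K, N + 1))
        xs = np.empty(L + 2)
        ys = np.empty(L + 2)
        for b in range(B):
            for i in range(K):
                # gather and insertion-sort this biomarker's event positions
                for j in range(L):
                    xs[j + 1] = position[b, i * L + j]
                    ys[j + 1] = thresholds[j]
                for j in range(2, L + 1):
                    xj, yj = xs[j], ys[j]
                    k = j - 1
                    while k >= 1 and xs[k] > xj:
                        xs[k + 1] = xs[k]
                        ys[k + 1] = ys[k]
                        k -= 1
                    xs[k + 1] = xj
                    ys[k + 1] = yj
                xs[0] = 0.0
                ys[0] = 0.0
                xs[L + 1] = float(N)
                ys[L + 1] = z_max
                seg = 0
                for s in range(N + 1):
                    while seg < L and xs[seg + 1] <= s:
                        seg += 1
                    dx = xs[seg + 1] - xs[seg]
                    if dx > 0.0:
                        t = (s - xs[seg]) / dx
                    else:
                        t = 1.0
                    out[b, i, s] = ys[seg] + t * (ys[seg + 1] - ys[seg])
                out[b, i, N] = z_max
        return out

    _HAVE_TRAJ_JIT = True
except ImportError:  # pragma: no cover
    _HAVE_TRAJ_JIT = False


def batch_trajectories(grid: EventGrid, orderings: np.ndarray,
                       stages: np.ndarray | None = None) -> np.ndarray:
    """Expected z for a batch of orderings: (B, K, len(stages)).

    ``stages`` defaults to the integer grid 0..N.  Stage positions are
    1-based: the event at position p of the ordering has occurred at stage
    p.  Fully vectorized — this is the hot path of ordering search.
    """
    orderings = np.atleast_2d(np.asarray(orderings, dtype=np.int64))
    B, N = orderings.shape
    if N != grid.n_events:
        raise ValueError("ordering length must equal the event count")
    K, L = grid.n_biomarkers, len(grid.thresholds)
    if stages is None:
        if _HAVE_TRAJ_JIT:
            position = np.empty((B, N))
            position[np.arange(B)[:, None], orderings] = np.arange(1, N + 1)
            return _batch_traj_jit(position,
                                   np.asarray(grid.thresholds, dtype=float),
                                   K, L, N, grid.z_max)
        stages = np.arange(N + 1, dtype=float)
    else:
        stages = np.atleast_1d(np.asarray(stages, dtype=float))
        if np.any(stages < 0) or np.any(stages > N):
            raise ValueError(f"stages must lie in [0, {N}]")
    S = len(stages)
    # position[b, e] = 1-based stage at which event e occurs
    position = np.empty((B, N))
    position[np.arange(B)[:, None], orderings] = np.arange(1, N + 1)
    # events are enumerated biomarker-major, so reshape groups per biomarker
    P = position.reshape(B, K, L)
    idx = np.argsort(P, axis=2, kind="stable")
    Ps = np.take_along_axis(P, idx, axis=2)
    Ts = np.broadcast_to(
        np.asarray(grid.thresholds), (B, K, L))
    Ts = np.take_along_axis(Ts, idx, axis=2)
    xp = np.concatenate(
        [np.zeros((B, K, 1)), Ps, np.full((B, K, 1), float(N))], axis=2)
    fp = np.concatenate(
        [np.zeros((B, K, 1)), Ts, np.full((B, K, 1), grid.z_max)], axis=2)
    # piecewise-linear evaluation; segment index via counting knots <= stage
    j = (xp[:, :, None, :] <= stages[None, None, :, None]).sum(axis=3) - 1
    j = np.clip(j, 0, L)                      # (B, K, S)
    x0 = np.take_along_axis(xp, j, axis=2)
    x1 = np.take_along_axis(xp, j + 1, axis=2)
    f0 = np.take_along_axis(fp, j, axis=2)
    f1 = np.take_along_axis(fp, j + 1, axis=2)
    dx = x1 - x0
    # a zero-length segment can only arise at stage N (an event in the last
    # position); the plateau value z_max wins there
    t = np.where(dx > 0, (stages[None, None, :] - x0) / np.where(dx > 0, dx, 1.0),
                 1.0)
    return f0 + t * (f1 - f0)


def trajectory_matrix(grid: EventGrid, ordering: np.ndarray,
                      stages: np.ndarray | None = None) -> np.ndarray:
    """Expected z for every biomarker at every stage, shape (K, len(stages))."""
    ordering = grid.validate_ordering(ordering)
    return batch_trajectories(grid, ordering[None], stages)[0]


def trajectory_value(grid: EventGrid, ordering: np.ndarray,
                     biomarker: int | str, stage: float) -> float:
    """Expected z-value of one biomarker at a (possibly fractional) stage."""
    if isinstance(biomarker, str):
        biomarker = grid.biomarkers.index(biomarker)
    return float(trajectory_matrix(grid, ordering, np.array([stage]))[biomarker, 0])


def stage_log_likelihood_matrix(z: np.ndarray, traj: np.ndarray,
                                sd: np.ndarray | float) -> np.ndarray:
    """Log N(z | traj, sd) summed over biomarkers, for every subject x stage.

    Parameters
    ----------
    z : (n, K) observed z-scores.
    traj : (K, S) expected values per biomarker per stage, or a batched
        (..., K, S) stack of trajectory matrices.
    sd : per-biomarker likelihood standard deviation (scalar or length K).

    Returns
    -------
    (..., n, S) array of log-likelihoods.

    Notes
    -----
    Uses the quadratic expansion
    ``-0.5 * (||z/sd||^2 - 2 (z/sd^2)·m + ||m/sd||^2) - const`` so that the
    subject x stage grid is a single matrix product — this is the inner loop
    of ordering search and MCMC.
    """
    z = np.asarray(z, dtype=float)
    traj = np.asarray(traj, dtype=float)
    n, K = z.shape
    if traj.shape[-2] != K:
        raise ValueError("trajectory/biomarker dimension mismatch")
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (K,))
    if np.any(sd <= 0):
        raise ValueError("likelihood sd must be positive")
    inv_var = 1.0 / sd**2
    const = 0.5 * K * _LOG_2PI + np.sum(np.log(sd))
    zz = np.sum(z**2 * inv_var, axis=1)  # (n,)
    batch = traj.shape[:-2]
    S = traj.shape[-1]
    flat = traj.reshape(-1, K, S)
    B = flat.shape[0]
    # (n, K) @ (K, B*S) — BLAS carries the whole subject x stage grid
    cross = ((z * inv_var) @ flat.transpose(1, 0, 2).reshape(K, B * S))
    cross = cross.reshape(n, B, S).transpose(1, 0, 2)     # (B, n, S)
    quad = (flat**2 * inv_var[None, :, None]).sum(axis=1)  # (B, S)
    ll = -0.5 * (zz[None, :, None] - 2.0 * cross + quad[:, None, :]) - const
    return ll.reshape(*batch, n, S)
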