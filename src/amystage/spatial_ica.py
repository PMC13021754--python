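"""Data-driven ROI discovery by spatial ICA on Centiloid volumes.

The voxel x subject data inside a group brain mask are decomposed into
spatially independent components (FastICA); each component map is scaled
to z-scores across mask voxels, thresholded at z > 1.96, intersected with
a gray-matter mask, and the gray-matter-dominant components become regions
of interest whose mean Centiloid values feed the progression model.

Component selection in practice is often done by visual inspection; here
it is made algorithmic via a tissue-dominance rule (mean GM probability
over a component's supra-threshold voxels must exceed the mean WM and CSF
probabilities), which is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "AnalysisMask",
    "ICResult",
    "build_group_mask",
    "decompose",
    "make_roi",
    "label_gm_dominant",
    "extract_roi_means",
    "derive_rois",
]


@dataclass
class AnalysisMask:
    """Boolean analysis mask with its derivation parameters."""

    mask: np.ndarray                      # boolean, 3D
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def build_group_mask(
    per_subject_tissue_maps: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    tissue_threshold: float = 0.20,
    participant_fraction: float = 0.50,
) -> AnalysisMask:
    """Group whole-brain mask from per-participant GM/WM/CSF probabilities.

    A voxel enters a participant's mask if any tissue probability exceeds
    ``tissue_threshold`` (default 20%); the group mask keeps voxels present
    in strictly more than ``participant_fraction`` (default 50%) of
    participants.
    """
    if not per_subject_tissue_maps:
        raise ValueError("no tissue maps given")
    shape = np.asarray(per_subject_tissue_maps[0][0]).shape
    counts = np.zeros(shape, dtype=int)
    for gm, wm, csf in per_subject_tissue_maps:
        maps = [np.asarray(m, dtype=float) for m in (gm, wm, csf)]
        if any(m.shape != shape for m in maps):
            raise ValueError("tissue maps must share one grid")
        passes = np.zeros(shape, dtype=bool)
        for m in maps:
            passes |= m > tissue_threshold
        counts += passes
    n = len(per_subject_tissue_maps)
    mask = counts > participant_fraction * n
    if not mask.any():
        raise ValueError("group mask is empty")
    return AnalysisMask(mask, {
        "tissue_threshold": tissue_threshold,
        "participant_fraction": participant_fraction,
        "n_participants": n,
    })


@dataclass
class ICResult:
    """Spatial ICA decomposition over mask voxels."""

    maps: np.ndarray          # (K, V) spatial component maps
    mixing: np.ndarray        # (n_subjects, K) per-subject weights
    mean: np.ndarray          # (n_subjects,) per-subject voxel mean removed
    seed: int | None
    converged: bool = True
    z_maps: np.ndarray | None = None       # (K, V) standardized maps
    roi_masks: np.ndarray | None = None    # (K, V) boolean
    usable: np.ndarray | None = None       # (K,) non-degenerate, nonempty ROI
    gm_dominant: np.ndarray | None = None  # (K,)

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Subjects x voxels reconstruction (mixing @ maps + mean)."""
        return self.mixing @ self.maps + self.mean[:, None]


def decompose(
    voxel_matrix: np.ndarray,
    n_components: int = 20,
    seed: int | None = None,
    max_retries: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    require_convergence: bool = True,
) -> ICResult:
    """Spatial FastICA of a subjects x mask-voxels matrix.

    Components are voxel maps (independent over voxels) and subjects index
    the mixing matrix; data are centred and whitened to exactly
    ``n_components`` principal components.  Each map's sign is fixed so
    its skewness is positive (amyloid loading is nonnegative).  On
    non-convergence the fit is retried with a fresh seed up to
    ``max_retries`` times, then rejected — unless ``require_convergence``
    is False (e.g. null simulations on unstructured data, where the
    fixed-point iteration has no stable target), in which case the last
    iterate is returned with ``converged=False``.
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("voxel_matrix must be 2D (subjects x voxels)")
    if not np.all(np.isfinite(X)):
        raise ValueError("voxel_matrix must be finite")
    n_subjects = X.shape[0]
    if n_subjects <= n_components:
        raise ValueError(
            f"need more subjects ({n_subjects}) than components "
            f"({n_components})"
        )
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rs = None if seed is None else seed + attempt
        ica = FastICA(n_components=n_components, random_state=rs,
                      whiten="unit-variance", tol=tol, max_iter=max_iter)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                # spatial ICA: voxels are the samples, subjects the features
                sources = ica.fit_transform(X.T)      # (V, K)
            except ConvergenceWarning as err:
                last_err = err
                if attempt < max_retries - 1 or require_convergence:
                    continue
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    sources = ica.fit_transform(X.T)
        maps = sources.T                              # (K, V)
        mixing = ica.mixing_                          # (n_subjects, K)
        flip = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
        maps = maps * flip[:, None]
        mixing = mixing * flip[None, :]
        return ICResult(maps=maps, mixing=mixing, mean=ica.mean_.copy(),
                        seed=rs, converged=converged)
    raise RuntimeError(
        f"FastICA failed to converge after {max_retries} retries"
    ) from last_err


def make_roi(
    ic_map: np.ndarray, gm_mask: np.ndarray, z_threshold: float = 1.96
) -> tuple[np.ndarray, bool]:
    """Threshold a component map into an ROI.

    The map is standardized to mean 0 / SD 1 across mask voxels (one-sided,
    consistent with positive-skew sign fixing) and voxels with
    z > ``z_threshold`` are intersected with the gray-matter mask.

    Returns ``(roi_mask, usable)``; a constant map or an empty ROI is
    flagged unusable.
    """
    ic_map = np.asarray(ic_map, dtype=float)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if ic_map.shape != gm_mask.shape:
        raise ValueError("component map and GM mask must share the voxel set")
    sd = ic_map.std()
    if sd < 1e-12:
        return np.zeros_like(gm_mask), False
    z = (ic_map - ic_map.mean()) / sd
    roi = (z > z_threshold) & gm_mask
    return roi, bool(roi.any())


def label_gm_dominant(
    z_supra_masks: np.ndarray,
    gm: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
) -> np.ndarray:
    """Label components whose supra-threshold voxels are predominantly
    gray matter: mean GM probability must exceed both mean WM and mean CSF
    over those voxels.  Components with no supra-threshold voxels are not
    dominant."""
    out = np.zeros(len(z_supra_masks), dtype=bool)
    for i, m in enumerate(np.asarray(z_supra_masks, dtype=bool)):
        if not m.any():
            continue
        out[i] = (gm[m].mean() > wm[m].mean()) and (gm[m].mean() > csf[m].mean())
    return out


def extract_roi_means(
    volumes: np.ndarray,
    roi_masks: np.ndarray,
    roi_names: list[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of each subject's volume over each ROI.

    ``volumes`` is (n, *grid) or (n, V); ``roi_masks`` is (R, *grid) or
    (R, V) boolean on the same voxel set.
    """
    volumes = np.asarray(volumes, dtype=float)
    roi_masks = np.asarray(roi_masks, dtype=bool)
    flat_v = volumes.reshape(volumes.shape[0], -1)
    flat_m = roi_masks.reshape(roi_masks.shape[0], -1)
    if flat_v.shape[1] != flat_m.shape[1]:
        raise ValueError("ROI masks do not match the volume grid")
    if np.any(~flat_m.any(axis=1)):
        raise ValueError("empty ROI mask")
    means = np.stack([flat_v[:, m].mean(axis=1) for m in flat_m], axis=1)
    if roi_names is None:
        roi_names = [f"roi_{i + 1}" for i in range(len(flat_m))]
    return pd.DataFrame(means, columns=roi_names)


def derive_rois(
    volumes: np.ndarray,
    analysis_mask: AnalysisMask,
    gm: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    n_components: int = 20,
    z_threshold: float = 1.96,
    gm_prob_threshold: float = 0.5,
    seed: int | None = None,
) -> ICResult:
    """End-to-end ROI discovery: decompose masked volumes, threshold each
    component, and label GM-dominant components.

    ``volumes`` is (n, *grid) in Centiloid; tissue maps live on the full
    grid.  Usable ROIs are those of GM-dominant components with nonempty
    thresholded masks.
    """
    mask = analysis_mask.mask
    X = np.asarray(volumes, dtype=float).reshape(len(volumes), -1)[:, mask.ravel()]
    res = decompose(X, n_components=n_components, seed=seed)
    V = X.shape[1]
    gm_m, wm_m, csf_m = (np.asarray(a, float).ravel()[mask.ravel()]
                         for a in (gm, wm, csf))
    gm_mask = gm_m > gm_prob_threshold
    z_maps = np.empty_like(res.maps)
    supra = np.zeros((res.n_components, V), dtype=bool)
    rois = np.zeros((res.n_components, V), dtype=bool)
    usable = np.zeros(res.n_components, dtype=bool)
    for i in range(res.n_components):
        sd = res.maps[i].std()
        z_maps[i] = 0.0 if sd < 1e-12 else (res.maps[i] - res.maps[i].mean()) / sd
        supra[i] = z_maps[i] > z_threshold
        rois[i], usable[i] = make_roi(res.maps[i], gm_mask, z_threshold)
    res.z_maps = z_maps
    res.roi_masks = rois
    res.gm_dominant = label_gm_dominant(supra, gm_m, wm_m, csf_m)
    res.usable = usable & res.gm_dominant
    return res
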