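"""Voxel time series, connectivity, spared gray matter, and lesion effects.

The simulator emulates resting-state fMRI with a three-level signal model:
each ROI belongs to a latent functional community; a voxel's series is

    community_weight * community_signal
    + roi_weight * roi_signal
    + noise_sd * voxel_noise,

all standard-normal processes.  Within-community ROI pairs therefore correlate
more strongly than between-community pairs, giving the connectivity matrix a
realistic block structure.

Connectivity is the element-wise exponential of the Pearson correlation matrix
of ROI mean time series, where each ROI mean is taken over its *non-lesioned*
gray-matter voxels.  An ROI entirely inside the lesion has no signal; its rows
and columns are set to 0 (a dead region must not masquerade as exp(0) = 1,
i.e. moderate connectivity).  Hence all nonzero entries lie in [e^-1, e^1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .atlas import LEFT, ToyAtlas
from .errors import AtlasIntegrityError, ConfigurationError, ContractError, DegenerateSignalError
from .lesion import LesionMask


@dataclass
class VoxelTimeseries:
    """T × V series over the atlas's gray-matter voxels.

    ``voxel_coords`` (V × 3) and ``voxel_roi`` (length V, 1-based ROI ids)
    tie columns back to the grid.
    """

    series: np.ndarray
    voxel_coords: np.ndarray
    voxel_roi: np.ndarray


def simulate_voxel_timeseries(atlas: ToyAtlas, n_timepoints: int = 120,
                              n_latent_communities: int = 4,
                              community_weight: float = 1.0,
                              roi_weight: float = 0.5,
                              noise_sd: float = 0.3,
                              seed: int = 0,
                              community_seed: int = 0) -> VoxelTimeseries:
    """Simulate gray-matter voxel time series with community structure.

    The ROI → community map is drawn from ``community_seed`` so that — as with
    real functional networks — the community layout is a property of the brain
    shared across subjects, while ``seed`` drives the per-subject realizations
    of the community, ROI, and voxel signals.
    """
    if n_timepoints < 8:
        raise ContractError("need at least 8 timepoints")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    N = atlas.n_rois
    coords = np.argwhere(atlas.gm_mask)
    voxel_roi = atlas.label_volume[atlas.gm_mask]

    roi_comm = np.random.default_rng(community_seed).integers(
        0, n_latent_communities, size=N)
    comm_sig = rng.standard_normal((n_timepoints, n_latent_communities))
    roi_sig = rng.standard_normal((n_timepoints, N))
    noise = rng.standard_normal((n_timepoints, len(coords)))

    series = (community_weight * comm_sig[:, roi_comm[voxel_roi - 1]]
              + roi_weight * roi_sig[:, voxel_roi - 1]
              + noise_sd * noise)
    return VoxelTimeseries(series=series, voxel_coords=coords, voxel_roi=voxel_roi)


def roi_mean_series(ts: VoxelTimeseries, atlas: ToyAtlas,
                    lesion: Optional[LesionMask] = None):
    """Mean series per ROI over non-lesioned voxels; zero if fully lesioned.

    Returns (T × N means, boolean alive mask).
    """
    N = atlas.n_rois
    T = ts.series.shape[0]
    if lesion is not None and lesion.mask.shape != atlas.grid_shape:
        raise ContractError("lesion grid does not match atlas grid")
    keep = np.ones(len(ts.voxel_roi), dtype=bool)
    if lesion is not None:
        keep = ~lesion.mask[tuple(ts.voxel_coords.T)]
    means = np.zeros((T, N))
    alive = np.zeros(N, dtype=bool)
    for roi in range(1, N + 1):
        cols = (ts.voxel_roi == roi) & keep
        if cols.any():
            means[:, roi - 1] = ts.series[:, cols].mean(axis=1)
            alive[roi - 1] = True
    return means, alive


def compute_connectivity(ts: VoxelTimeseries, atlas: ToyAtlas,
                         lesion: Optional[LesionMask] = None) -> np.ndarray:
    """Exponentiated Pearson-correlation connectivity matrix X.

    Rows/columns of fully lesioned ROIs are zero; everything else lies in
    [e^-1, e^1] with diagonal e^1.
    """
    means, alive = roi_mean_series(ts, atlas, lesion)
    N = atlas.n_rois
    sd = means[:, alive].std(axis=0)
    if np.any(sd < 1e-12):
        roi = int(np.flatnonzero(alive)[np.argmin(sd)]) + 1
        raise DegenerateSignalError(
            f"ROI {roi} has zero-variance mean time series")
    X = np.zeros((N, N))
    corr = np.corrcoef(means[:, alive].T)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    idx = np.flatnonzero(alive)
    X[np.ix_(idx, idx)] = np.exp(corr)
    return X


def spared_fraction(atlas: ToyAtlas, lesion: Optional[LesionMask] = None) -> np.ndarray:
    """Per-ROI fraction of gray-matter voxels outside the lesion (p_i)."""
    counts = atlas.roi_gm_counts()
    if np.any(counts == 0):
        bad = int(np.flatnonzero(counts == 0)[0]) + 1
        raise AtlasIntegrityError(f"ROI {bad} has zero gray-matter voxels")
    if lesion is None:
        return np.ones(atlas.n_rois)
    if lesion.mask.shape != atlas.grid_shape:
        raise ContractError("lesion grid does not match atlas grid")
    lesioned_labels = atlas.label_volume[lesion.mask & atlas.gm_mask]
    lesioned = np.bincount(lesioned_labels, minlength=atlas.n_rois + 1)[1:]
    return 1.0 - lesioned / counts


def corrupt_connectivity(X: np.ndarray, p: np.ndarray, attenuation: float = 0.5,
                         noise_sd: float = 0.1, seed: int = 0) -> np.ndarray:
    """Diminish and perturb connectivity touching lesioned ROIs.

    Entries (i, j) where i or j is partially lesioned (0 < p < 1) become
    clip(attenuation·X_ij + ε, min(X), max(X)) with symmetric Gaussian ε.
    Fully lesioned rows/columns stay zero; intact pairs are untouched.
    """
    if not (0.0 < attenuation <= 1.0):
        raise ConfigurationError("attenuation must be in (0, 1]")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    p = np.asarray(p, dtype=float)
    lesioned = p < 1.0
    dead = p == 0.0
    touch = lesioned[:, None] | lesioned[None, :]
    dead_pair = dead[:, None] | dead[None, :]
    modify = touch & ~dead_pair
    if not modify.any():
        out = X.copy()
        out[dead_pair] = 0.0
        return out

    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=X.shape) if noise_sd > 0 else np.zeros_like(X)
    eps = np.triu(eps) + np.triu(eps, 1).T  # shared across (i,j) and (j,i)
    vmin, vmax = X.min(), X.max()
    out = X.copy()
    out[modify] = np.clip(attenuation * X[modify] + eps[modify], vmin, vmax)
    out[dead_pair] = 0.0
    return out


def hemisphere_spared_fraction(atlas: ToyAtlas, lesion: Optional[LesionMask],
                               hemisphere: int = LEFT) -> float:
    hemi_vol = atlas.hemisphere_volume()
    region = hemi_vol == hemisphere
    total = int(region.sum())
    if total == 0:
        raise AtlasIntegrityError("hemisphere contains no gray matter")
    if lesion is None:
        return 1.0
    return 1.0 - int((region & lesion.mask).sum()) / total


def territory_spared_fraction(atlas: ToyAtlas, lesion: LesionMask) -> float:
    terr = atlas.territory_volume() == lesion.host_territory
    return 1.0 - int((terr & lesion.mask).sum()) / int(terr.sum())


def whole_brain_spared_fraction(atlas: ToyAtlas, lesion: Optional[LesionMask]) -> float:
    if lesion is None:
        return 1.0
    return 1.0 - int((atlas.gm_mask & lesion.mask).sum()) / int(atlas.gm_mask.sum())


def rescale_score(y_healthy: float, atlas: ToyAtlas,
                  lesion: Optional[LesionMask],
                  mode: str = "left_hemisphere") -> float:
    """Attenuate a healthy 0–100 score proportionally to spared gray matter.

    ``mode`` selects the region over which sparing is measured:
    ``left_hemisphere`` (default; language-dominant hemisphere),
    ``whole_brain``, or ``territory`` (the lesion's host territory).
    """
    if not (0.0 <= y_healthy <= 100.0):
        raise ContractError("healthy score must lie in [0, 100]")
    if lesion is None:
        return float(y_healthy)
    if mode == "left_hemisphere":
        s = hemisphere_spared_fraction(atlas, lesion, LEFT)
    elif mode == "whole_brain":
        s = whole_brain_spared_fraction(atlas, lesion)
    elif mode == "territory":
        s = territory_spared_fraction(atlas, lesion)
    else:
        raise ConfigurationError(f"unknown rescale mode {mode!r}")
    return float(y_healthy * s)
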