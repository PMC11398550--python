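"""Synthetic subject cohorts: toy brain, lesion, corrupted connectivity, score.

A cohort stands in for both the lesion-augmented healthy reference data
(hundreds of subjects with simulated lesions inserted into clean scans) and
small patient datasets.  One atlas is shared; per subject the pipeline is

    time series  ->  lesion  ->  connectivity (lesioned voxels excluded)
                 ->  corruption (attenuate + noise + clip)  ->  p (spared GM)
    healthy score -> rescaled by spared gray matter -> observed score

Every step is sub-seeded deterministically from the cohort seed, so the entire
cohort is a pure function of (configs, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ToyAtlas, build_toy_atlas
from .errors import ContractError
from .lesion import LesionMask, sample_lesion
from .signals import (compute_connectivity, corrupt_connectivity, rescale_score,
                      simulate_voxel_timeseries, spared_fraction)

_SEED_STRIDE = 1_000_003  # per-subject sub-seed derivation, kept below 2**31


@dataclass(frozen=True)
class AtlasConfig:
    grid_shape: tuple = (24, 24, 24)
    n_rois: int = 60
    n_territories_per_hemisphere: int = 3
    seed: int = 0


@dataclass(frozen=True)
class TimeseriesConfig:
    """Voxel time-series simulation settings.

    ``n_timepoints`` defaults to 1200, the length of one standard
    resting-state run in the healthy reference data the simulator emulates.
    ``community_weight_jitter`` gives each subject a latent community-coupling
    trait u ~ U(-1, 1): the subject's community weight is
    community_weight * (1 + jitter * u), so coupling strength varies across
    individuals and is expressed in their connectivity.
    """

    n_timepoints: int = 1200
    n_latent_communities: int = 4
    community_weight: float = 1.0
    community_weight_jitter: float = 0.0
    roi_weight: float = 0.5
    noise_sd: float = 0.3
    community_seed: int = 0  # community layout is shared across subjects


@dataclass(frozen=True)
class LesionConfig:
    enabled: bool = True
    fraction_range: tuple = (0.05, 0.20)
    attenuation: float = 0.5
    noise_sd: float = 0.1


@dataclass(frozen=True)
class ScoreConfig:
    """Healthy-score distribution and lesion-to-score coupling.

    Healthy scores are Normal(mean, sd) truncated to [0, 100].  When
    ``connectivity_weight`` is nonzero, connectivity_weight * u is added to
    the healthy score, where u is the subject's latent community-coupling
    trait (see TimeseriesConfig.community_weight_jitter) — planting a genuine
    dependence of behavior on network coherence that the connectivity matrix
    expresses.  ``rescale_mode`` picks the region over which spared gray
    matter attenuates the score (left_hemisphere / whole_brain / territory).
    """

    mean: float = 85.0
    sd: float = 10.0
    rescale_mode: str = "left_hemisphere"
    connectivity_weight: float = 0.0


@dataclass
class SyntheticSubject:
    id: str
    X: np.ndarray
    p: np.ndarray
    y_healthy: float
    y_observed: float
    lesion: Optional[LesionMask]
    seed: int


@dataclass
class Cohort:
    """Shared atlas plus per-subject data, with stacked array views."""

    atlas: ToyAtlas
    subjects: list
    config: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def connectivity(self) -> np.ndarray:
        return np.stack([s.X for s in self.subjects])

    @property
    def spared(self) -> np.ndarray:
        return np.stack([s.p for s in self.subjects])

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.y_observed for s in self.subjects])

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "id": s.id,
                "seed": s.seed,
                "y_healthy": s.y_healthy,
                "y_observed": s.y_observed,
                "lesion_territory": s.lesion.host_territory if s.lesion else -1,
                "lesion_size_fraction": s.lesion.size_fraction if s.lesion else 0.0,
                "lesion_voxels": s.lesion.n_voxels if s.lesion else 0,
            })
        return pd.DataFrame(rows)


def _truncnorm_draw(rng, mean, sd, lo=0.0, hi=100.0, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(n_subjects: int,
                    atlas_config: AtlasConfig = AtlasConfig(),
                    ts_config: TimeseriesConfig = TimeseriesConfig(),
                    lesion_config: LesionConfig = LesionConfig(),
                    score_config: ScoreConfig = ScoreConfig(),
                    seed: int = 0,
                    atlas: Optional[ToyAtlas] = None) -> Cohort:
    """Generate a deterministic synthetic cohort.

    A pre-built ``atlas`` may be passed to share work across cohorts; it must
    then match ``atlas_config``'s intent (the config is still recorded).
    """
    if n_subjects < 1:
        raise ContractError("n_subjects must be >= 1")
    if atlas is None:
        atlas = build_toy_atlas(atlas_config.grid_shape, atlas_config.n_rois,
                                atlas_config.n_territories_per_hemisphere,
                                seed=atlas_config.seed)

    subjects = []
    draws_rng = np.random.default_rng(seed)
    y_base = _truncnorm_draw(draws_rng, score_config.mean, score_config.sd,
                             size=n_subjects)

    for m in range(n_subjects):
        sub_seed = (seed * _SEED_STRIDE + 7919 * m + 1) % (2 ** 31)
        # latent community-coupling trait, expressed in the time series and
        # (optionally) in the behavioral score
        u = float(np.random.default_rng(sub_seed + 3).uniform(-1.0, 1.0))
        w_comm = ts_config.community_weight * (
            1.0 + ts_config.community_weight_jitter * u)
        ts = simulate_voxel_timeseries(
            atlas, ts_config.n_timepoints, ts_config.n_latent_communities,
            w_comm, ts_config.roi_weight,
            ts_config.noise_sd, seed=sub_seed,
            community_seed=ts_config.community_seed)
        lesion = None
        if lesion_config.enabled:
            lesion = sample_lesion(atlas, lesion_config.fraction_range,
                                   seed=sub_seed + 1)
        X = compute_connectivity(ts, atlas, lesion=lesion)
        p = spared_fraction(atlas, lesion)
        if lesion is not None:
            X = corrupt_connectivity(X, p, lesion_config.attenuation,
                                     lesion_config.noise_sd, seed=sub_seed + 2)
        y_h = float(np.clip(y_base[m] + score_config.connectivity_weight * u,
                            0.0, 100.0))
        y_obs = rescale_score(y_h, atlas, lesion, mode=score_config.rescale_mode)
        subjects.append(SyntheticSubject(
            id=f"sub-{m:04d}", X=X, p=p, y_healthy=y_h, y_observed=y_obs,
            lesion=lesion, seed=sub_seed))

    config = {
        "n_subjects": n_subjects,
        "seed": seed,
        "atlas": asdict(atlas_config),
        "timeseries": asdict(ts_config),
        "lesion": asdict(lesion_config),
        "score": asdict(score_config),
    }
    return Cohort(atlas=atlas, subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# documented experiment presets
#
# The planted-signal preset defines the synthetic study conditions used for
# signal-recovery and transfer experiments: a tight healthy-score distribution
# (sd 3 around 85), territory-level score rescaling (so a 5–20% territory
# lesion moves the observed score by a recoverable margin), and a latent
# community-coupling trait (jitter 0.2) that shapes both the connectivity and
# the score (weight 3).  The transfer target preset shifts the healthy-score
# mean to 65 to emulate a cohort with different severity.


def planted_signal_ts_config() -> TimeseriesConfig:
    return TimeseriesConfig(community_weight_jitter=0.2)


def planted_signal_score_config() -> ScoreConfig:
    return ScoreConfig(mean=85.0, sd=3.0, rescale_mode="territory",
                       connectivity_weight=3.0)


def shifted_target_score_config() -> ScoreConfig:
    return replace(planted_signal_score_config(), mean=65.0)


def planted_signal_cohort(n_subjects: int, seed: int = 0,
                          atlas: Optional[ToyAtlas] = None,
                          score_config: Optional[ScoreConfig] = None) -> Cohort:
    """Cohort whose score depends on spared gray matter and network coherence."""
    return generate_cohort(
        n_subjects,
        atlas_config=AtlasConfig(),
        ts_config=planted_signal_ts_config(),
        lesion_config=LesionConfig(),
        score_config=score_config or planted_signal_score_config(),
        seed=seed,
        atlas=atlas,
    )
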