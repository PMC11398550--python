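"""File formats: connectivity CSV, NIfTI volumes, cohort directories, configs.

Connectivity matrices are stored as plain CSV for inspectability; atlas label
volumes and lesion masks go through NIfTI (nibabel) so real lesion masks can be
swapped in.  A cohort directory holds one matrix per subject, a manifest CSV,
and a YAML snapshot of the generating configuration — enough metadata to
regenerate the cohort bit-for-bit from the same code version.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import ToyAtlas
from .cohort import Cohort
from .errors import FormatError
from .lesion import LesionMask

_SYMMETRY_TOL = 1e-8


def write_connectivity(X: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(X, dtype=float), delimiter=",", fmt="%.17g")


def read_connectivity(path) -> np.ndarray:
    try:
        X = np.genfromtxt(path, delimiter=",")
    except ValueError as e:
        raise FormatError(f"{path}: not a numeric CSV matrix ({e})") from e
    X = np.atleast_2d(X)
    if X.shape[0] != X.shape[1]:
        raise FormatError(f"{path}: matrix is {X.shape[0]}x{X.shape[1]}, not square")
    bad = np.argwhere(~np.isfinite(X))
    if len(bad):
        i, j = bad[0]
        raise FormatError(f"{path}: non-finite entry at row {i}, column {j}")
    asym = np.abs(X - X.T).max()
    if asym > _SYMMETRY_TOL:
        raise FormatError(f"{path}: asymmetric by {asym:.3g} (tolerance {_SYMMETRY_TOL})")
    if asym > 0:
        warnings.warn(f"{path}: symmetrizing (max asymmetry {asym:.3g})")
        X = (X + X.T) / 2.0
    return X


def write_volume(volume: np.ndarray, path) -> None:
    """Write an integer label volume or boolean mask as NIfTI."""
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError("volumes must be integer-valued (labels or 0/1 masks)")
    nib.save(nib.Nifti1Image(data.astype(np.int32), affine=np.eye(4)), str(path))


def read_volume(path, expect_shape: Optional[tuple] = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path}: volume has non-integer values")
    data = np.round(data).astype(np.int32)
    if expect_shape is not None and tuple(data.shape) != tuple(expect_shape):
        raise FormatError(f"{path}: grid {data.shape} does not match expected {tuple(expect_shape)}")
    return data


def write_atlas(atlas: ToyAtlas, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.label_volume, directory / "labels.nii.gz")
    write_volume(atlas.gm_mask, directory / "gm_mask.nii.gz")
    meta = {
        "roi_hemisphere": atlas.roi_hemisphere.tolist(),
        "roi_territory": atlas.roi_territory.tolist(),
        "grid_shape": list(atlas.grid_shape),
    }
    (directory / "atlas.json").write_text(json.dumps(meta))


def read_atlas(directory) -> ToyAtlas:
    directory = Path(directory)
    meta = json.loads((directory / "atlas.json").read_text())
    labels = read_volume(directory / "labels.nii.gz", tuple(meta["grid_shape"]))
    gm = read_volume(directory / "gm_mask.nii.gz", tuple(meta["grid_shape"]))
    return ToyAtlas(
        label_volume=labels,
        gm_mask=gm.astype(bool),
        roi_hemisphere=np.array(meta["roi_hemisphere"], dtype=np.int8),
        roi_territory=np.array(meta["roi_territory"], dtype=np.int32),
        grid_shape=tuple(meta["grid_shape"]),
    )


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    try:
        if str(path).endswith(".json"):
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise FormatError(f"{path}: cannot parse config ({e})") from e


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# cohort directories


def export_cohort(cohort: Cohort, directory, write_masks: bool = True) -> Path:
    """Write manifest, per-subject matrices/spared fractions, and config."""
    directory = Path(directory)
    (directory / "connectivity").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    paths, ppaths = [], []
    spared = pd.DataFrame(cohort.spared,
                          columns=[f"roi_{i + 1}" for i in range(cohort.atlas.n_rois)])
    spared.insert(0, "id", manifest["id"])
    spared.to_csv(directory / "spared_fractions.csv", index=False)
    for subj in cohort.subjects:
        rel = f"connectivity/{subj.id}.csv"
        write_connectivity(subj.X, directory / rel)
        paths.append(rel)
        ppaths.append("spared_fractions.csv")
    manifest["connectivity_path"] = paths
    manifest["spared_path"] = ppaths
    manifest.to_csv(directory / "manifest.csv", index=False)
    save_config(cohort.config, directory / "config.yaml")
    write_atlas(cohort.atlas, directory / "atlas")
    if write_masks:
        masks = directory / "lesions"
        masks.mkdir(exist_ok=True)
        for subj in cohort.subjects:
            if subj.lesion is not None:
                write_volume(subj.lesion.mask, masks / f"{subj.id}.nii.gz")
    return directory


class LoadedCohort:
    """Array-backed cohort read from disk (duck-types Cohort for training)."""

    def __init__(self, connectivity, spared, scores, manifest, atlas=None):
        self.connectivity = connectivity
        self.spared = spared
        self.scores = scores
        self._manifest = manifest
        self.atlas = atlas

    @property
    def n_subjects(self):
        return len(self._manifest)

    def manifest(self):
        return self._manifest


def load_cohort(directory) -> LoadedCohort:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    if manifest["id"].duplicated().any():
        raise FormatError("manifest has duplicate subject ids")
    if not manifest["y_observed"].between(0, 100).all():
        raise FormatError("manifest scores must lie in [0, 100]")
    Xs = []
    for rel in manifest["connectivity_path"]:
        f = directory / rel
        if not f.exists():
            raise FormatError(f"missing connectivity file {f}")
        Xs.append(read_connectivity(f))
    spared_df = pd.read_csv(directory / "spared_fractions.csv")
    spared = spared_df.drop(columns=["id"]).to_numpy(dtype=float)
    atlas = read_atlas(directory / "atlas") if (directory / "atlas/atlas.json").exists() else None
    return LoadedCohort(
        connectivity=np.stack(Xs),
        spared=spared,
        scores=manifest["y_observed"].to_numpy(dtype=float),
        manifest=manifest,
        atlas=atlas,
    )


def lesion_from_volume(path, host_territory: int, atlas: ToyAtlas) -> LesionMask:
    """Read a 0/1 NIfTI mask as a LesionMask on the atlas grid."""
    data = read_volume(path, expect_shape=atlas.grid_shape)
    mask = data.astype(bool)
    terr = atlas.territory_volume() == host_territory
    count = int(terr.sum())
    return LesionMask(mask=mask, host_territory=host_territory,
                      size_fraction=float((mask & terr).sum()) / count if count else 0.0)
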