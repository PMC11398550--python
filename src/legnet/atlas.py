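"""Toy volumetric brain atlas.

A :class:`ToyAtlas` is a desk-scale stand-in for a real parcellation (e.g. a
246-region atlas) combined with an arterial-territory map.  It lives on a small
3-D voxel grid: an ellipsoidal "brain" mask is split into left/right
hemispheres at the x-midline, each hemisphere is cut into arterial territories
(contiguous slabs along y), and each territory is parcellated into contiguous
ROIs by seeded multi-source breadth-first growth.  Every ROI therefore lies
wholly inside one hemisphere and one territory, which is what the lesion
simulator relies on.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import AtlasIntegrityError, SizingError

LEFT = 0
RIGHT = 1

#: 6-connected neighborhood offsets (face neighbors only).
NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass
class ToyAtlas:
    """Voxel-grid parcellation with gray-matter mask and ROI annotations.

    Attributes
    ----------
    label_volume:
        3-D int array; 0 = background, 1..N = ROI id.
    gm_mask:
        3-D bool array marking gray-matter voxels.
    roi_hemisphere:
        length-N array over {LEFT, RIGHT} (index i-1 holds ROI i).
    roi_territory:
        length-N array of arterial-territory ids in 1..2T (left territories
        first).
    grid_shape:
        the (x, y, z) grid dimensions.
    """

    label_volume: np.ndarray
    gm_mask: np.ndarray
    roi_hemisphere: np.ndarray
    roi_territory: np.ndarray
    grid_shape: tuple = field(default=None)

    def __post_init__(self):
        if self.grid_shape is None:
            self.grid_shape = tuple(self.label_volume.shape)

    @property
    def n_rois(self) -> int:
        return len(self.roi_hemisphere)

    @property
    def territories(self) -> np.ndarray:
        return np.unique(self.roi_territory)

    def left_territories(self) -> np.ndarray:
        """Territory ids whose ROIs lie in the left hemisphere."""
        return np.unique(self.roi_territory[self.roi_hemisphere == LEFT])

    def roi_gm_counts(self) -> np.ndarray:
        """Gray-matter voxel count per ROI (index i-1 for ROI i)."""
        labels = self.label_volume[self.gm_mask]
        return np.bincount(labels, minlength=self.n_rois + 1)[1:]

    def territory_volume(self) -> np.ndarray:
        """Voxel-wise territory-id map (0 outside gray matter)."""
        terr = np.zeros(self.grid_shape, dtype=np.int32)
        lut = np.concatenate([[0], self.roi_territory.astype(np.int32)])
        terr[self.gm_mask] = lut[self.label_volume[self.gm_mask]]
        return terr

    def territory_gm_count(self, territory: int) -> int:
        return int(np.sum(self.territory_volume() == territory))

    def hemisphere_volume(self) -> np.ndarray:
        """Voxel-wise hemisphere map (−1 outside gray matter)."""
        hemi = np.full(self.grid_shape, -1, dtype=np.int8)
        lut = np.concatenate([[-1], self.roi_hemisphere.astype(np.int8)])
        hemi[self.gm_mask] = lut[self.label_volume[self.gm_mask]]
        return hemi

    def validate(self) -> None:
        """Raise :class:`AtlasIntegrityError` on any violated invariant."""
        counts = self.roi_gm_counts()
        if np.any(counts < 1):
            bad = int(np.flatnonzero(counts < 1)[0]) + 1
            raise AtlasIntegrityError(f"ROI {bad} labels no gray-matter voxel")
        mid = self.grid_shape[0] // 2
        xs = np.argwhere(self.label_volume > 0)[:, 0]
        labels = self.label_volume[self.label_volume > 0]
        voxel_hemi = (xs >= mid).astype(np.int8)
        for roi in range(1, self.n_rois + 1):
            hemis = np.unique(voxel_hemi[labels == roi])
            if len(hemis) != 1 or hemis[0] != self.roi_hemisphere[roi - 1]:
                raise AtlasIntegrityError(f"ROI {roi} crosses the x-midline")


def _ellipsoid_mask(grid_shape) -> np.ndarray:
    sx, sy, sz = grid_shape
    x, y, z = np.ogrid[:sx, :sy, :sz]
    cx, cy, cz = (sx - 1) / 2.0, (sy - 1) / 2.0, (sz - 1) / 2.0
    rx, ry, rz = 0.48 * sx, 0.48 * sy, 0.48 * sz
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _split_counts(total: int, parts: int) -> list:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _voronoi_parcellate(coords: np.ndarray, n_parcels: int, first_label: int,
                        out: np.ndarray, rng: np.random.Generator) -> None:
    """Partition ``coords`` into contiguous parcels by multi-source BFS.

    Seeds are drawn without replacement; ties are resolved by BFS visit order,
    which is deterministic for a given rng state.  Labels are written into
    ``out`` starting at ``first_label``.
    """
    inside = np.zeros(out.shape, dtype=bool)
    inside[tuple(coords.T)] = True
    seed_idx = rng.choice(len(coords), size=n_parcels, replace=False)
    queue = deque()
    for j, si in enumerate(seed_idx):
        c = tuple(coords[si])
        out[c] = first_label + j
        queue.append(c)
    while queue:
        cx, cy, cz = queue.popleft()
        lab = out[cx, cy, cz]
        for dx, dy, dz in NEIGHBOR_OFFSETS:
            nx, ny, nz = cx + dx, cy + dy, cz + dz
            if (0 <= nx < out.shape[0] and 0 <= ny < out.shape[1]
                    and 0 <= nz < out.shape[2] and inside[nx, ny, nz]
                    and out[nx, ny, nz] == 0):
                out[nx, ny, nz] = lab
                queue.append((nx, ny, nz))


def build_toy_atlas(grid_shape=(24, 24, 24), n_rois: int = 60,
                    n_territories_per_hemisphere: int = 3,
                    seed: int = 0) -> ToyAtlas:
    """Build a deterministic toy atlas.

    Parameters
    ----------
    grid_shape:
        (x, y, z) voxel grid dimensions; x must be even so the midline splits
        the grid into equal hemispheres.
    n_rois:
        total number of ROIs; must be even and ≥ 4 so both hemispheres get the
        same count.
    n_territories_per_hemisphere:
        number of arterial territories per hemisphere; ids 1..T are LEFT,
        T+1..2T are RIGHT.
    seed:
        seeds parcel-seed placement; the same seed reproduces the atlas
        exactly.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if grid_shape[0] % 2 != 0:
        raise SizingError("grid x-dimension must be even to split hemispheres")
    if n_rois < 4 or n_rois % 2 != 0:
        raise SizingError("n_rois must be even and at least 4")
    T = int(n_territories_per_hemisphere)
    if T < 1:
        raise SizingError("need at least one territory per hemisphere")
    if n_rois // 2 < T:
        raise SizingError("fewer ROIs per hemisphere than territories")

    brain = _ellipsoid_mask(grid_shape)
    if brain.sum() < 8 * n_rois:
        raise SizingError(
            f"grid {grid_shape} has {int(brain.sum())} brain voxels; "
            f"need at least {8 * n_rois} for {n_rois} ROIs (≥ 8 voxels each)")

    rng = np.random.default_rng(seed)
    mid = grid_shape[0] // 2
    labels = np.zeros(grid_shape, dtype=np.int32)
    roi_hemisphere = np.empty(n_rois, dtype=np.int8)
    roi_territory = np.empty(n_rois, dtype=np.int32)

    next_label = 1
    for hemi, hemi_id in ((LEFT, 0), (RIGHT, 1)):
        coords = np.argwhere(brain)
        coords = coords[(coords[:, 0] < mid) if hemi == LEFT else (coords[:, 0] >= mid)]
        # contiguous territories: near-equal-size slabs along y
        order = np.lexsort((coords[:, 2], coords[:, 0], coords[:, 1]))
        coords = coords[order]
        slab_sizes = _split_counts(len(coords), T)
        roi_counts = _split_counts(n_rois // 2, T)
        start = 0
        for t_local, (size, n_t) in enumerate(zip(slab_sizes, roi_counts)):
            terr_id = hemi_id * T + t_local + 1
            terr_coords = coords[start:start + size]
            start += size
            if len(terr_coords) < n_t:
                raise SizingError(
                    f"territory {terr_id} has {len(terr_coords)} voxels for "
                    f"{n_t} ROIs")
            _voronoi_parcellate(terr_coords, n_t, next_label, labels, rng)
            roi_hemisphere[next_label - 1:next_label - 1 + n_t] = hemi
            roi_territory[next_label - 1:next_label - 1 + n_t] = terr_id
            next_label += n_t

    atlas = ToyAtlas(
        label_volume=labels,
        gm_mask=labels > 0,
        roi_hemisphere=roi_hemisphere,
        roi_territory=roi_territory,
        grid_shape=grid_shape,
    )
    atlas.validate()
    return atlas
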