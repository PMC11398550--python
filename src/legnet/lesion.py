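"""Simulated stroke lesions by constrained random region growing.

A lesion is a voxel mask obeying four geometric rules: (1) it lies in the left
hemisphere only; (2) it is confined to a single arterial territory; (3) its
volume is 5–20% of that territory's gray matter; (4) it is spatially
continuous (6-connected) and simply-connected (no interior holes).

The sampler picks a left territory uniformly at random, draws a target size
uniformly from the allowed fraction range, grows the mask by randomized
frontier expansion over the 6-neighborhood, fills interior holes, and — if
filling overshoots the size cap — trims boundary voxels that do not break
connectivity.  A handful of seeded retries guards against rare degenerate
growths; the whole procedure is a pure function of (atlas, range, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atlas import LEFT, NEIGHBOR_OFFSETS, ToyAtlas
from .errors import ConfigurationError, SizingError

_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class LesionMask:
    """Boolean stroke-lesion mask on the atlas grid.

    ``size_fraction`` is the lesioned share of the host territory's
    gray-matter voxels.
    """

    mask: np.ndarray
    host_territory: int
    size_fraction: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def is_six_connected(mask: np.ndarray) -> bool:
    if not mask.any():
        return False
    _, n = ndimage.label(mask, structure=_STRUCTURE_6)
    return n == 1


def is_hole_free(mask: np.ndarray) -> bool:
    """True iff morphological hole filling leaves the mask unchanged."""
    return bool(np.array_equal(ndimage.binary_fill_holes(mask, structure=_STRUCTURE_6), mask))


def _grow(territory_mask: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Randomized 6-connected region growing to ``target`` voxels."""
    coords = np.argwhere(territory_mask)
    start = coords[rng.integers(len(coords))]
    mask = np.zeros(territory_mask.shape, dtype=bool)
    mask[tuple(start)] = True
    in_frontier = np.zeros(territory_mask.shape, dtype=bool)
    frontier = []

    def push_neighbors(v):
        for off in NEIGHBOR_OFFSETS:
            n = v + off
            if np.all(n >= 0) and np.all(n < mask.shape):
                t = tuple(n)
                if territory_mask[t] and not mask[t] and not in_frontier[t]:
                    in_frontier[t] = True
                    frontier.append(n)

    push_neighbors(start)
    while mask.sum() < target and frontier:
        i = rng.integers(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        in_frontier[tuple(v)] = False
        mask[tuple(v)] = True
        push_neighbors(v)
    return mask


def _trim(mask: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Remove boundary voxels (keeping 6-connectivity and hole-freeness)
    until the mask has at most ``cap`` voxels."""
    mask = mask.copy()
    while mask.sum() > cap:
        eroded = ndimage.binary_erosion(mask, structure=_STRUCTURE_6, border_value=0)
        boundary = np.argwhere(mask & ~eroded)
        order = rng.permutation(len(boundary))
        removed = False
        for i in order:
            v = tuple(boundary[i])
            mask[v] = False
            if is_six_connected(mask) and is_hole_free(mask):
                removed = True
                break
            mask[v] = True
        if not removed:
            return mask  # caller treats over-cap as a failed attempt
    return mask


def sample_lesion(atlas: ToyAtlas, fraction_range=(0.05, 0.20),
                  seed: int = 0, max_attempts: int = 25) -> LesionMask:
    """Draw one lesion satisfying all four geometric rules.

    Parameters
    ----------
    atlas:
        toy atlas providing gray matter, hemispheres and territories.
    fraction_range:
        (low, high) lesion size as a fraction of the host territory's
        gray-matter volume; must lie strictly inside (0, 1).
    seed:
        seeds host choice, target size, growth and trimming; identical seeds
        yield identical masks.
    """
    lo, hi = float(fraction_range[0]), float(fraction_range[1])
    if not (0.0 < lo <= hi < 1.0):
        raise ConfigurationError(f"fraction_range {fraction_range} not inside (0, 1)")
    left = atlas.left_territories()
    if len(left) == 0:
        raise ConfigurationError("atlas has no left-hemisphere territory")

    terr_vol = atlas.territory_volume()
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        host = int(rng.choice(left))
        territory_mask = terr_vol == host
        count = int(territory_mask.sum())
        lo_cap = int(np.ceil(lo * count))
        hi_cap = int(np.floor(hi * count))
        if lo_cap < 1 or count == 0:
            raise SizingError(
                f"territory {host} has {count} gray-matter voxels; too small "
                f"to host a lesion at fraction {lo}")
        if lo_cap > hi_cap:
            raise SizingError(
                f"territory {host} ({count} voxels) admits no integer lesion "
                f"size within fractions [{lo}, {hi}]")

        target = int(round(rng.uniform(lo, hi) * count))
        target = min(max(target, lo_cap), hi_cap)
        mask = _grow(territory_mask, target, rng)
        if mask.sum() < lo_cap:  # frontier exhausted (fragmented territory)
            continue
        filled = ndimage.binary_fill_holes(mask, structure=_STRUCTURE_6)
        if np.any(filled & ~territory_mask):
            continue  # a cavity reached outside the territory; re-draw
        mask = filled
        if mask.sum() > hi_cap:
            mask = _trim(mask, hi_cap, rng)
        n = int(mask.sum())
        if (lo_cap <= n <= hi_cap and is_six_connected(mask)
                and is_hole_free(mask)):
            return LesionMask(mask=mask, host_territory=host,
                              size_fraction=n / count)
    raise SizingError(
        f"could not grow a valid lesion in {max_attempts} attempts (seed {seed})")


def check_lesion_geometry(atlas: ToyAtlas, lesion: LesionMask,
                          fraction_range=(0.05, 0.20)) -> dict:
    """Evaluate every geometric rule; returns a dict of named booleans.

    Used by the test suite and the reproduction script to audit sampled
    lesions against the four rules.
    """
    terr_vol = atlas.territory_volume()
    hemi_vol = atlas.hemisphere_volume()
    vox = lesion.mask
    in_gm = bool(np.all(atlas.gm_mask[vox]))
    terrs = np.unique(terr_vol[vox]) if vox.any() else np.array([])
    hemis = np.unique(hemi_vol[vox]) if vox.any() else np.array([])
    count = int(np.sum(terr_vol == lesion.host_territory))
    frac = vox.sum() / count if count else np.nan
    return {
        "nonempty": bool(vox.any()),
        "within_gray_matter": in_gm,
        "left_hemisphere_only": len(hemis) == 1 and hemis[0] == LEFT,
        "single_territory": len(terrs) == 1 and terrs[0] == lesion.host_territory,
        "six_connected": is_six_connected(vox),
        "hole_free": is_hole_free(vox),
        "size_in_range": bool(fraction_range[0] <= frac + 1e-12
                              and frac - 1e-12 <= fraction_range[1]),
        "size_fraction": float(frac),
    }
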