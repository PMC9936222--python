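"""Construction of grey-level texture matrices from a discretized ROI.

All matrices use the 3D "merged" aggregation: GLCM and GLRLM pool the 13
unique 3D directions into a single matrix; GLSZM, GLDZM, NGTDM and NGLDM
are computed once per VOI. Zones are 26-connected equal-level components.
GLDZM zone distances use the 6-connected city-block distance to the ROI
border, with border voxels at distance 1 (voxels outside the image grid
count as border).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["TextureMatrices", "build_texture_matrices", "DIRECTIONS_3D"]

# 13 unique direction vectors covering the 26-neighbourhood up to sign
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_CONN26 = ndimage.generate_binary_structure(3, 3)
_NEIGHBOR_KERNEL = _CONN26.astype(float).copy()
_NEIGHBOR_KERNEL[1, 1, 1] = 0.0


@dataclass
class TextureMatrices:
    """Dense texture matrices for one ROI.

    Rows index grey levels 1..Ng throughout. Column meaning varies:
    co-occurring level (glcm), run length (glrlm), zone size (glszm),
    zone distance (gldzm), dependence count (ngldm).
    """

    glcm: np.ndarray  # (Ng, Ng) symmetric pair counts, merged over 13 directions
    glrlm: np.ndarray  # (Ng, max_run) run counts, merged over 13 directions
    glszm: np.ndarray  # (Ng, max_zone) zone-size counts
    gldzm: np.ndarray  # (Ng, max_dist) zone-distance counts
    ngtdm_p: np.ndarray  # (Ng,) level probabilities over valid voxels
    ngtdm_s: np.ndarray  # (Ng,) summed |level - neighbourhood average|
    ngtdm_n: int  # number of voxels with a valid neighbourhood
    ngldm: np.ndarray  # (Ng, max_dependence) dependence counts
    n_levels: int
    n_voxels: int
    n_directions: int = len(DIRECTIONS_3D)


def _glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    cm = np.zeros((ng, ng), dtype=float)
    shape = levels.shape
    for d in DIRECTIONS_3D:
        src = [slice(max(0, -o), min(s, s - o)) for o, s in zip(d, shape)]
        dst = [slice(max(0, o), min(s, s + o)) for o, s in zip(d, shape)]
        a = levels[tuple(src)].ravel()
        b = levels[tuple(dst)].ravel()
        ok = (a > 0) & (b > 0)
        np.add.at(cm, (a[ok] - 1, b[ok] - 1), 1.0)
    return cm + cm.T  # symmetric merge: count both orientations


def _glrlm(levels: np.ndarray, ng: int) -> np.ndarray:
    shape = levels.shape
    max_run = max(shape)
    # allow diagonal runs up to the shortest traversal bound
    rlm = np.zeros((ng, max_run), dtype=float)
    idx = np.indices(shape)
    for d in DIRECTIONS_3D:
        # a line starts where the previous voxel along -d falls off-grid
        starts = np.zeros(shape, dtype=bool)
        for ax, o in enumerate(d):
            if o == 1:
                starts |= idx[ax] == 0
            elif o == -1:
                starts |= idx[ax] == shape[ax] - 1
        for x, y, z in np.argwhere(starts):
            run_level, run_len = 0, 0
            cx, cy, cz = int(x), int(y), int(z)
            while 0 <= cx < shape[0] and 0 <= cy < shape[1] and 0 <= cz < shape[2]:
                lev = int(levels[cx, cy, cz])
                if lev == run_level:
                    run_len += 1
                else:
                    if run_level > 0:
                        rlm[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lev, 1
                cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
            if run_level > 0:
                rlm[run_level - 1, run_len - 1] += 1
    used = np.nonzero(rlm.sum(axis=0))[0]
    return rlm[:, : used[-1] + 1] if used.size else rlm[:, :1]


def _zones(levels: np.ndarray, ng: int) -> list[tuple[int, np.ndarray]]:
    """26-connected equal-level zones as (level, voxel index array) pairs."""
    zones = []
    for lev in range(1, ng + 1):
        labeled, n = ndimage.label(levels == lev, structure=_CONN26)
        for z in range(1, n + 1):
            zones.append((lev, np.argwhere(labeled == z)))
    return zones


def _distance_map(mask: np.ndarray) -> np.ndarray:
    """City-block distance to the ROI border; border voxels get 1."""
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[1:-1, 1:-1, 1:-1]


def _ngtdm(levels: np.ndarray, mask: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray, int]:
    lv = levels.astype(float)
    nbr_sum = ndimage.convolve(lv, _NEIGHBOR_KERNEL, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask.astype(float), _NEIGHBOR_KERNEL, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0)
    avg = np.zeros_like(lv)
    avg[valid] = nbr_sum[valid] / nbr_cnt[valid]
    s = np.zeros(ng)
    counts = np.zeros(ng)
    for lev in range(1, ng + 1):
        sel = valid & (levels == lev)
        counts[lev - 1] = sel.sum()
        s[lev - 1] = np.abs(lev - avg[sel]).sum()
    total = counts.sum()
    p = counts / total if total > 0 else counts
    return p, s, int(total)


def _ngldm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    # dependence count j = 1 + number of 26-neighbours with the same level
    max_dep = 27
    mat = np.zeros((ng, max_dep), dtype=float)
    for lev in range(1, ng + 1):
        sel = levels == lev
        same = ndimage.convolve(sel.astype(float), _NEIGHBOR_KERNEL, mode="constant", cval=0.0)
        deps = same[sel & mask].astype(int) + 1
        np.add.at(mat, (lev - 1, deps - 1), 1.0)
    used = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : used[-1] + 1] if used.size else mat[:, :1]


def build_texture_matrices(level_grid: np.ndarray, mask: np.ndarray) -> TextureMatrices:
    """Build all texture matrices for a discretized ROI.

    Parameters
    ----------
    level_grid
        3D integer grid; grey levels 1..Ng inside the ROI (values outside
        the mask are ignored).
    mask
        3D boolean ROI mask, same shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    levels = np.where(mask, np.asarray(level_grid, dtype=np.int64), 0)
    if levels[mask].min() < 1:
        raise ValueError("grey levels inside the ROI must be >= 1")
    ng = int(levels.max())
    n_vox = int(mask.sum())

    zones = _zones(levels, ng)
    max_zone = max(len(v) for _, v in zones)
    szm = np.zeros((ng, max_zone), dtype=float)
    dist_map = _distance_map(mask)
    max_dist = int(dist_map[mask].max())
    dzm = np.zeros((ng, max_dist), dtype=float)
    for lev, voxels in zones:
        szm[lev - 1, len(voxels) - 1] += 1
        zone_dist = int(dist_map[tuple(voxels.T)].min())
        dzm[lev - 1, zone_dist - 1] += 1

    p_i, s_i, n_valid = _ngtdm(levels, mask, ng)
    return TextureMatrices(
        glcm=_glcm(levels, ng),
        glrlm=_glrlm(levels, ng),
        glszm=szm,
        gldzm=dzm,
        ngtdm_p=p_i,
        ngtdm_s=s_i,
        ngtdm_n=n_valid,
        ngldm=_ngldm(levels, mask, ng),
        n_levels=ng,
        n_voxels=n_vox,
    )
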