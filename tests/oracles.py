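"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: zones are found
by explicit stack-based flood fill, runs by walking every voxel's line,
border distances by breadth-first search, Tomek links by a direct O(n^2)
scan, and Mann-Whitney p-values by full enumeration of group
assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
NEIGHBORS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def zones_flood_fill(levels: np.ndarray) -> list[tuple[int, list[tuple[int, int, int]]]]:
    """26-connected equal-level zones by explicit flood fill (level 0 = outside)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if seen[x, y, z] or levels[x, y, z] == 0:
                    continue
                lev = int(levels[x, y, z])
                stack = [(x, y, z)]
                seen[x, y, z] = True
                members = []
                while stack:
                    cx, cy, cz = stack.pop()
                    members.append((cx, cy, cz))
                    for dx, dy, dz in NEIGHBORS_26:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]
                            and not seen[nx, ny, nz] and levels[nx, ny, nz] == lev
                        ):
                            seen[nx, ny, nz] = True
                            stack.append((nx, ny, nz))
                zones.append((lev, members))
    return zones


def glszm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    zones = zones_flood_fill(levels)
    max_size = max(len(m) for m in (v for _, v in zones))
    mat = np.zeros((ng, max_size))
    for lev, members in zones:
        mat[lev - 1, len(members) - 1] += 1
    return mat


def border_distance_bfs(mask: np.ndarray) -> np.ndarray:
    """City-block (6-connected) distance to ROI border; border voxels = 1."""
    shape = mask.shape
    dist = np.full(shape, -1, dtype=int)
    queue = []
    for x, y, z in np.argwhere(mask):
        for dx, dy, dz in NEIGHBORS_6:
            nx, ny, nz = x + dx, y + dy, z + dz
            outside = not (
                0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]
            ) or not mask[nx, ny, nz]
            if outside:
                dist[x, y, z] = 1
                queue.append((x, y, z))
                break
    while queue:
        nxt = []
        for x, y, z in queue:
            for dx, dy, dz in NEIGHBORS_6:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]
                    and mask[nx, ny, nz] and dist[nx, ny, nz] < 0
                ):
                    dist[nx, ny, nz] = dist[x, y, z] + 1
                    nxt.append((nx, ny, nz))
        queue = nxt
    return dist


def gldzm_brute(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    dist = border_distance_bfs(mask)
    zones = zones_flood_fill(np.where(mask, levels, 0))
    max_d = int(dist[mask].max())
    mat = np.zeros((ng, max_d))
    for lev, members in zones:
        d = min(dist[m] for m in members)
        mat[lev - 1, d - 1] += 1
    return mat


def glrlm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    """Merged 13-direction run counts: each voxel either starts a run
    (its predecessor differs) and the run is walked forward, or it does not."""
    shape = levels.shape

    def at(p):
        x, y, z = p
        if 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
            return int(levels[x, y, z])
        return -1

    runs: dict[tuple[int, int], int] = {}
    for d in DIRECTIONS:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    lev = at((x, y, z))
                    if lev <= 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if at(prev) == lev:
                        continue  # not a run start
                    length = 1
                    cur = (x + d[0], y + d[1], z + d[2])
                    while at(cur) == lev:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    runs[(lev, length)] = runs.get((lev, length), 0) + 1
    max_len = max(l for _, l in runs)
    mat = np.zeros((ng, max_len))
    for (lev, length), count in runs.items():
        mat[lev - 1, length - 1] += count
    return mat


def glcm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    shape = levels.shape
    mat = np.zeros((ng, ng))
    for d in DIRECTIONS:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = int(levels[x, y, z])
                    nx, ny, nz = x + d[0], y + d[1], z + d[2]
                    if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                        continue
                    b = int(levels[nx, ny, nz])
                    if a > 0 and b > 0:
                        mat[a - 1, b - 1] += 1
                        mat[b - 1, a - 1] += 1
    return mat


def tomek_score_brute(X: np.ndarray, y: np.ndarray) -> float:
    """O(n^2) Tomek-link borderline fraction with z-scored features."""
    X = np.asarray(X, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    n = Z.shape[0]
    nn = []
    for i in range(n):
        best, best_d = None, np.inf
        for j in range(n):
            if i == j:
                continue
            d = float(np.sum((Z[i] - Z[j]) ** 2))
            if d < best_d:  # strict: ties keep the lowest index
                best, best_d = j, d
        nn.append(best)
    linked = set()
    for i in range(n):
        j = nn[i]
        if nn[j] == i and y[i] != y[j]:
            linked.add(i)
            linked.add(j)
    return len(linked) / n


def mwu_enumerate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_min(idx_a: tuple[int, ...]) -> float:
        ga = pooled[list(idx_a)]
        gb = pooled[[i for i in range(len(pooled)) if i not in idx_a]]
        ua = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
        return min(ua, len(ga) * len(gb) - ua)

    observed = u_min(tuple(range(na)))
    us = [u_min(idx) for idx in combinations(range(len(pooled)), na)]
    p = sum(u <= observed for u in us) / len(us)
    return observed, p
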