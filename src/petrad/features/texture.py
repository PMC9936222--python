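"""Texture features computed from grey-level matrices.

The run-length, size-zone, distance-zone and dependence families share
one algebraic structure (emphasis sums over a level x count matrix);
a single helper evaluates it and each family maps the results onto its
IBSI identifiers. Zero denominators yield 0 by convention.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrices

__all__ = ["texture_features", "glcm_features"]


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence (``cm.*``) features from a symmetric GLCM."""
    total = glcm.sum()
    if total == 0:
        return {k: 0.0 for k in _CM_NAMES}
    p = glcm / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float(np.sum(i * px))
    var = float(np.sum((ii - mu) ** 2 * p))

    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    diff_avg = float(np.sum(k_diff * p_diff))
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    sum_avg = float(np.sum(k_sum * p_sum))

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))

    off = ii != jj
    autocorr = float(np.sum(ii * jj * p))
    corr = (autocorr - mu * mu) / var if var > 0 else 0.0
    return {
        "cm.joint.max": float(p.max()),
        "cm.joint.avg": mu,
        "cm.joint.var": var,
        "cm.joint.entr": hxy,
        "cm.diff.avg": diff_avg,
        "cm.diff.var": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "cm.diff.entr": _entropy2(p_diff),
        "cm.sum.avg": sum_avg,
        "cm.sum.var": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "cm.sum.entr": _entropy2(p_sum),
        "cm.energy": float(np.sum(p**2)),
        "cm.contrast": float(np.sum((ii - jj) ** 2 * p)),
        "cm.dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "cm.inv.diff": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "cm.inv.diff.norm": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "cm.inv.diff.mom": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "cm.inv.diff.mom.norm": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "cm.inv.var": float(np.sum(p[off] / (ii - jj)[off] ** 2)),
        "cm.corr": corr,
        "cm.auto.corr": autocorr,
        "cm.clust.tend": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "cm.clust.shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "cm.clust.prom": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "cm.info.corr.1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "cm.info.corr.2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
    }


_CM_NAMES = (
    "cm.joint.max cm.joint.avg cm.joint.var cm.joint.entr cm.diff.avg cm.diff.var "
    "cm.diff.entr cm.sum.avg cm.sum.var cm.sum.entr cm.energy cm.contrast "
    "cm.dissimilarity cm.inv.diff cm.inv.diff.norm cm.inv.diff.mom cm.inv.diff.mom.norm "
    "cm.inv.var cm.corr cm.auto.corr cm.clust.tend cm.clust.shade cm.clust.prom "
    "cm.info.corr.1 cm.info.corr.2"
).split()


def _emphasis_family(mat: np.ndarray, n_voxel_base: float) -> dict[str, float]:
    """Shared run/zone/distance/dependence algebra.

    ``mat[i-1, j-1]`` counts entities of grey level i with size/length/
    distance/dependence j; ``n_voxel_base`` is the denominator for the
    percentage feature.
    """
    n = mat.sum()
    if n == 0:
        raise ValueError("empty texture matrix")
    p = mat / n
    ng, nj = mat.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    mi = mat.sum(axis=1)
    mj = mat.sum(axis=0)
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    return {
        "j.low": float(np.sum(mat / jj**2) / n),
        "j.high": float(np.sum(mat * jj**2) / n),
        "i.low": float(np.sum(mat / ii**2) / n),
        "i.high": float(np.sum(mat * ii**2) / n),
        "ji.lowlow": float(np.sum(mat / (ii**2 * jj**2)) / n),
        "j.low.i.high": float(np.sum(mat * ii**2 / jj**2) / n),
        "j.high.i.low": float(np.sum(mat * jj**2 / ii**2) / n),
        "ji.highhigh": float(np.sum(mat * ii**2 * jj**2) / n),
        "glnu": float(np.sum(mi**2) / n),
        "glnu.norm": float(np.sum(mi**2) / n**2),
        "jnu": float(np.sum(mj**2) / n),
        "jnu.norm": float(np.sum(mj**2) / n**2),
        "perc": float(n / n_voxel_base) if n_voxel_base > 0 else 0.0,
        "gl.var": float(np.sum((ii - mu_i) ** 2 * p)),
        "j.var": float(np.sum((jj - mu_j) ** 2 * p)),
        "entr": _entropy2(p.ravel()),
        "energy": float(np.sum(p**2)),
    }


def _rename(vals: dict[str, float], prefix: str, mapping: dict[str, str]) -> dict[str, float]:
    return {f"{prefix}.{new}": vals[old] for old, new in mapping.items()}


_RLM_MAP = {
    "j.low": "sre", "j.high": "lre", "i.low": "lgre", "i.high": "hgre",
    "ji.lowlow": "srlge", "j.low.i.high": "srhge", "j.high.i.low": "lrlge",
    "ji.highhigh": "lrhge", "glnu": "glnu", "glnu.norm": "glnu.norm",
    "jnu": "rlnu", "jnu.norm": "rlnu.norm", "perc": "r.perc",
    "gl.var": "gl.var", "j.var": "rl.var", "entr": "rl.entr",
}
_SZM_MAP = {
    "j.low": "sze", "j.high": "lze", "i.low": "lgze", "i.high": "hgze",
    "ji.lowlow": "szlge", "j.low.i.high": "szhge", "j.high.i.low": "lzlge",
    "ji.highhigh": "lzhge", "glnu": "glnu", "glnu.norm": "glnu.norm",
    "jnu": "zsnu", "jnu.norm": "zsnu.norm", "perc": "z.perc",
    "gl.var": "gl.var", "j.var": "zs.var", "entr": "zs.entr",
}
_DZM_MAP = {
    "j.low": "sde", "j.high": "lde", "i.low": "lgze", "i.high": "hgze",
    "ji.lowlow": "sdlge", "j.low.i.high": "sdhge", "j.high.i.low": "ldlge",
    "ji.highhigh": "ldhge", "glnu": "glnu", "glnu.norm": "glnu.norm",
    "jnu": "zdnu", "jnu.norm": "zdnu.norm", "perc": "z.perc",
    "gl.var": "gl.var", "j.var": "zd.var", "entr": "zd.entr",
}
_NGL_MAP = {
    "j.low": "lde", "j.high": "hde", "i.low": "lgce", "i.high": "hgce",
    "ji.lowlow": "ldlge", "j.low.i.high": "ldhge", "j.high.i.low": "hdlge",
    "ji.highhigh": "hdhge", "glnu": "glnu", "glnu.norm": "glnu.norm",
    "jnu": "dcnu", "jnu.norm": "dcnu.norm", "perc": "dc.perc",
    "gl.var": "gl.var", "j.var": "dc.var", "entr": "dc.entr",
    "energy": "dc.energy",
}

_COARSENESS_CAP = 1e6


def _ngtdm_features(p: np.ndarray, s: np.ndarray, n_valid: int) -> dict[str, float]:
    i = np.arange(1, p.size + 1, dtype=float)
    occ = p > 0
    n_gp = int(occ.sum())
    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP

    if n_gp <= 1 or n_valid == 0:
        contrast = busyness = complexity = strength = 0.0
    else:
        io, po, so = i[occ], p[occ], s[occ]
        di = io[:, None] - io[None, :]
        pp = po[:, None] * po[None, :]
        contrast = float(np.sum(pp * di**2) / (n_gp * (n_gp - 1)) * s.sum() / n_valid)
        bden = float(np.sum(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :])))
        busyness = ps / bden if bden > 0 else 0.0
        psum = po[:, None] + po[None, :]
        complexity = float(
            np.sum(np.abs(di) * (po[:, None] * so[:, None] + po[None, :] * so[None, :]) / psum)
            / n_valid
        )
        ssum = float(s.sum())
        strength = float(np.sum(psum * di**2)) / ssum if ssum > 0 else 0.0
    return {
        "ngt.coarseness": coarseness,
        "ngt.contrast": contrast,
        "ngt.busyness": busyness,
        "ngt.complexity": complexity,
        "ngt.strength": strength,
    }


def texture_features(matrices: TextureMatrices) -> dict[str, float]:
    """All cm.*, rlm.*, szm.*, dzm.*, ngt.* and ngl.* features."""
    nv = matrices.n_voxels
    out = glcm_features(matrices.glcm)
    out.update(
        _rename(_emphasis_family(matrices.glrlm, nv * matrices.n_directions), "rlm", _RLM_MAP)
    )
    out.update(_rename(_emphasis_family(matrices.glszm, nv), "szm", _SZM_MAP))
    out.update(_rename(_emphasis_family(matrices.gldzm, nv), "dzm", _DZM_MAP))
    out.update(_ngtdm_features(matrices.ngtdm_p, matrices.ngtdm_s, matrices.ngtdm_n))
    out.update(_rename(_emphasis_family(matrices.ngldm, nv), "ngl", _NGL_MAP))
    return out
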