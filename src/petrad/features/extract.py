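"""Full feature-vector extraction for one delineated lesion."""

from __future__ import annotations

from typing import Literal

import numpy as np

from ..io import PETVolume, ROIMask
from ..manifest import feature_manifest
from .discretize import DiscretizationConfig, discretize
from .matrices import build_texture_matrices
from .statistics import (
    intensity_histogram_features,
    intensity_volume_histogram_features,
    local_intensity_features,
    morphology_features,
    statistical_features,
)
from .texture import texture_features

__all__ = ["extract_all", "FeatureVector"]


class FeatureVector(dict):
    """Ordered identifier -> value map for one lesion, tagged SUV or TBR."""

    def __init__(self, values: dict[str, float], dataset: str):
        super().__init__(values)
        self.dataset = dataset


def _bounding_box(mask: np.ndarray, margin: int = 1) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def extract_all(
    volume: PETVolume,
    lesion: ROIMask,
    config: DiscretizationConfig | None = None,
    dataset_tag: Literal["SUV", "TBR"] = "SUV",
) -> FeatureVector:
    """Extract the full 154-feature manifest from one lesion.

    The SUV and TBR configurations run through the identical code path;
    only the input intensities differ (TBR volumes are SUV volumes
    scaled by 1/background-mean upstream).
    """
    config = config or DiscretizationConfig()
    mask = lesion.data
    if not mask.any():
        raise ValueError("lesion mask is empty")
    values = volume.data[mask]

    out: dict[str, float] = {}
    out.update(statistical_features(values))
    levels = discretize(values, config)
    ng = config.n_bins if config.method == "fixed_bin_number" else int(levels.max())
    out.update(intensity_histogram_features(levels, ng))
    out.update(intensity_volume_histogram_features(values))
    out.update(local_intensity_features(volume.data, mask, volume.spacing))
    out.update(morphology_features(mask, volume.spacing))

    box = _bounding_box(mask)
    level_grid = np.zeros(volume.data.shape, dtype=np.int64)
    level_grid[mask] = levels
    matrices = build_texture_matrices(level_grid[box], mask[box])
    out.update(texture_features(matrices))

    manifest = feature_manifest()
    missing = set(manifest) - set(out)
    if missing:
        raise RuntimeError(f"extractor did not produce: {sorted(missing)}")
    ordered = {name: float(out[name]) for name in manifest}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite feature values for: {bad}")
    return FeatureVector(ordered, dataset_tag)
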