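"""Grey-level discretization of ROI intensities.

Two IBSI schemes are supported:

* ``fixed_bin_size`` — level = floor((x - min) / w) + 1, with the bin
  origin anchored either at the ROI minimum or at a fixed value. The
  number of levels then depends on the intensity range, so features
  built on the discretized grid are generally *not* invariant under a
  positive rescaling of the input (e.g. TBR normalization).
* ``fixed_bin_number`` — level = min(floor(Ng*(x - min)/(max - min)) + 1, Ng),
  which is invariant under any positive affine rescaling.

A constant ROI maps to a single occupied level 1 in both schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["DiscretizationConfig", "discretize"]


@dataclass(frozen=True)
class DiscretizationConfig:
    """How ROI intensities are binned into grey levels 1..Ng."""

    method: Literal["fixed_bin_size", "fixed_bin_number"] = "fixed_bin_size"
    bin_width: float = 0.1
    n_bins: int = 16
    min_policy: Literal["roi_min", "fixed_value"] = "roi_min"
    fixed_min: float = 0.0

    def __post_init__(self) -> None:
        if self.method == "fixed_bin_size":
            if not self.bin_width > 0:
                raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        elif self.method == "fixed_bin_number":
            if self.n_bins < 2:
                raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        else:
            raise ValueError(f"unknown discretization method {self.method!r}")


def discretize(values: np.ndarray, config: DiscretizationConfig) -> np.ndarray:
    """Map intensities to integer grey levels 1..Ng.

    Parameters
    ----------
    values
        ROI intensities, any shape; must be non-empty.
    config
        Binning scheme.

    Returns
    -------
    Integer array of the same shape with levels starting at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty ROI")
    vmin = values.min()
    vmax = values.max()
    if config.method == "fixed_bin_size":
        origin = vmin if config.min_policy == "roi_min" else config.fixed_min
        levels = np.floor((values - origin) / config.bin_width).astype(np.int64) + 1
        # the ROI minimum itself always falls in bin 1 under roi_min anchoring
        return np.maximum(levels, 1)
    ng = config.n_bins
    if vmax == vmin:
        return np.ones_like(values, dtype=np.int64)
    levels = np.floor(ng * (values - vmin) / (vmax - vmin)).astype(np.int64) + 1
    return np.minimum(levels, ng)
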