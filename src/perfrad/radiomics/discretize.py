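"""Gray-level discretization of in-mask intensities.

Two schemes:

* ``fixed_bin_width(w)`` (default, w = 25 map units):
  ``level = floor((x - min_in_mask) / w) + 1``;
* ``fixed_bin_count(k)``: k equal-width bins over the in-mask range.

A constant region maps to the single level 1.  Levels are 0 outside the
mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedImage:
    levels: np.ndarray     # int volume, 1..n_levels in mask, 0 outside
    n_levels: int
    scheme: str
    mask: np.ndarray

    def in_mask(self) -> np.ndarray:
        """Flat array of in-mask levels."""
        return self.levels[self.mask]


def discretize(
    image: np.ndarray,
    mask: np.ndarray,
    scheme: str = "fixed_bin_width",
    bin_width: float = 25.0,
    bin_count: int = 32,
    max_levels: int = 4096,
) -> DiscretizedImage:
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if scheme == "fixed_bin_width":
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        lv = np.floor((vals - lo) / bin_width).astype(np.int32) + 1
    elif scheme == "fixed_bin_count":
        if bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        span = hi - lo
        if span == 0:
            lv = np.ones(vals.shape, dtype=np.int32)
        else:
            lv = np.minimum(np.floor((vals - lo) / (span / bin_count)).astype(np.int32) + 1, bin_count)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    n_levels = int(lv.max())
    if n_levels > max_levels:
        raise ValueError(f"discretization produced {n_levels} levels (> {max_levels}); increase bin_width")
    levels[mask] = lv
    label = f"{scheme}({bin_width if scheme == 'fixed_bin_width' else bin_count})"
    return DiscretizedImage(levels=levels, n_levels=n_levels, scheme=label, mask=mask)
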