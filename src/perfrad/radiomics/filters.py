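"""Image filter bank applied before feature extraction.

Families:

* ``original`` — identity;
* ``log_sigma`` — Laplacian of Gaussian at a physical scale sigma (mm),
  converted to voxels through the spacing;
* ``wavelet`` — one-level separable 3D decomposition (coif1), each of the
  8 subbands (LLL..HHH, L=low/approximation, H=high/detail, axis order
  x,y,z) reconstructed back to image size;
* ``square`` / ``square_root`` / ``logarithm`` / ``exponential`` —
  monotone remaps of the min-max normalized intensity, rescaled back to
  the original range so downstream fixed-bin-width discretization stays
  comparable across filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
REMAP_FAMILIES = ("square", "square_root", "logarithm", "exponential")
WAVELET_KERNEL = "coif1"


@dataclass(frozen=True)
class FilterSpec:
    """One filter of the bank; ``label`` names feature columns."""

    family: str
    sigma: float | None = None      # mm, log_sigma only
    subband: str | None = None      # wavelet only

    def __post_init__(self):
        families = ("original", "log_sigma", "wavelet") + REMAP_FAMILIES
        if self.family not in families:
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.family == "log_sigma":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("log_sigma requires sigma > 0")
        elif self.sigma is not None:
            raise ValueError("sigma only valid for log_sigma")
        if self.family == "wavelet":
            if self.subband not in WAVELET_SUBBANDS:
                raise ValueError(f"wavelet requires subband in {WAVELET_SUBBANDS}")
        elif self.subband is not None:
            raise ValueError("subband only valid for wavelet")

    @property
    def label(self) -> str:
        if self.family == "log_sigma":
            s = self.sigma
            s_txt = str(int(s)) if float(s).is_integer() else str(s)
            return f"log-sigma-{s_txt}"
        if self.family == "wavelet":
            return f"wavelet-{self.subband}"
        return self.family.replace("_", "-")


def default_filter_bank(
    log_sigmas=LOG_SIGMAS_MM,
    wavelet_subbands=WAVELET_SUBBANDS,
    remaps=REMAP_FAMILIES,
    include_original: bool = True,
) -> list[FilterSpec]:
    """The full default bank: original, 5 LoG scales, 8 wavelet subbands,
    4 intensity remaps (18 filtered images per map)."""
    bank = []
    if include_original:
        bank.append(FilterSpec("original"))
    bank += [FilterSpec("log_sigma", sigma=s) for s in log_sigmas]
    bank += [FilterSpec("wavelet", subband=sb) for sb in wavelet_subbands]
    bank += [FilterSpec(f) for f in remaps]
    return bank


def _wavelet_subband(image: np.ndarray, subband: str) -> np.ndarray:
    coeffs = pywt.dwtn(image, WAVELET_KERNEL, mode="symmetric")
    key = subband.replace("L", "a").replace("H", "d").lower()
    zeroed = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
    recon = pywt.idwtn(zeroed, WAVELET_KERNEL, mode="symmetric")
    return recon[tuple(slice(0, s) for s in image.shape)]


def _remap(image: np.ndarray, family: str) -> np.ndarray:
    lo, hi = float(np.min(image)), float(np.max(image))
    span = hi - lo
    if span == 0:
        return image.astype(float).copy()
    u = (image - lo) / span
    if family == "square":
        g = u ** 2
    elif family == "square_root":
        g = np.sqrt(u)
    elif family == "logarithm":
        g = np.log1p(u) / np.log(2.0)
    elif family == "exponential":
        g = np.expm1(u) / (np.e - 1.0)
    else:  # pragma: no cover
        raise ValueError(family)
    return lo + span * g


def apply_filter(image: np.ndarray, spec: FilterSpec, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Apply one filter of the bank; output has the input's shape."""
    image = np.asarray(image, dtype=float)
    if spec.family == "original":
        return image.copy()
    if spec.family == "log_sigma":
        sigma_vox = [spec.sigma / s for s in spacing]
        return ndimage.gaussian_laplace(image, sigma_vox)
    if spec.family == "wavelet":
        return _wavelet_subband(image, spec.subband)
    return _remap(image, spec.family)
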