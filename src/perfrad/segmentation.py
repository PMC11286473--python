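"""Region delineation on perfusion, diffusion and derived maps.

Three tissue compartments are delineated per subject:

* **ischemic** — hypoperfused tissue, ``Tmax > 6 s`` on the DSC-PWI
  time-to-maximum map;
* **infarct** — irreversibly damaged core, ``ADC < 620e-6 mm^2/s`` on the
  apparent diffusion coefficient map derived from a DWI pair;
* **hypoxic** — grid units of the affected hemisphere whose venous oxygen
  saturation falls below 0.7 (see :mod:`perfrad.svo2`).

All thresholds are strict inequalities; boundary voxels are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Hypoperfusion threshold on the Tmax map (seconds); ischemic = Tmax > 6 s.
ISCHEMIC_TMAX_THRESHOLD_S: float = 6.0

#: Infarct-core threshold on the ADC map (mm^2/s); infarct = ADC < 620e-6.
INFARCT_ADC_THRESHOLD: float = 620e-6

PERFUSION_MAPS = ("CBF", "CBV", "MTT", "Tmax")


@dataclass
class ADCMap:
    """Apparent diffusion coefficient volume with a validity mask.

    ``adc`` is in mm^2/s.  ``valid_mask`` marks voxels where both DWI
    signals were strictly positive so the log-ratio is defined; outside it
    ``adc`` is NaN.
    """

    adc: np.ndarray
    valid_mask: np.ndarray


@dataclass
class RegionMask:
    """A binary region on the common voxel grid."""

    mask: np.ndarray
    region_kind: str  # ischemic | infarct | hypoxic
    threshold_used: float
    threshold_units: str = ""

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def compute_adc(dwi_b0: np.ndarray, dwi_b1000: np.ndarray, b: float = 1000.0) -> ADCMap:
    """Compute the ADC map from a DWI pair.

    ADC = -(1/b) * ln(S_b / S_0) per voxel, with ``b`` in s/mm^2 so the
    result is in mm^2/s.  Voxels where either signal is <= 0 are flagged
    invalid and set to NaN.
    """
    if b <= 0:
        raise ValueError(f"diffusion weighting b must be > 0, got {b}")
    dwi_b0 = np.asarray(dwi_b0, dtype=float)
    dwi_b1000 = np.asarray(dwi_b1000, dtype=float)
    if dwi_b0.shape != dwi_b1000.shape:
        raise ValueError(f"DWI shape mismatch: {dwi_b0.shape} vs {dwi_b1000.shape}")
    valid = (dwi_b0 > 0) & (dwi_b1000 > 0)
    adc = np.full(dwi_b0.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = -np.log(dwi_b1000[valid] / dwi_b0[valid]) / b
    return ADCMap(adc=adc, valid_mask=valid)


def segment_threshold(
    volume: np.ndarray,
    brain_mask: np.ndarray,
    rule: str,
    threshold: float,
    region_kind: str = "custom",
    threshold_units: str = "",
) -> RegionMask:
    """Strict-inequality threshold segmentation inside the brain mask.

    ``rule`` is ``"greater_than"`` or ``"less_than"``; the comparison is
    strict, so boundary voxels are never included.  NaN voxels (e.g.
    invalid ADC) never satisfy either rule.  An empty result is valid.
    """
    volume = np.asarray(volume, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if volume.shape != brain_mask.shape:
        raise ValueError(f"shape mismatch: {volume.shape} vs {brain_mask.shape}")
    with np.errstate(invalid="ignore"):
        if rule == "greater_than":
            mask = volume > threshold
        elif rule == "less_than":
            mask = volume < threshold
        else:
            raise ValueError(f"unknown rule {rule!r}; use 'greater_than' or 'less_than'")
    mask &= brain_mask
    return RegionMask(mask=mask, region_kind=region_kind, threshold_used=threshold, threshold_units=threshold_units)


def segment_ischemic(tmax: np.ndarray, brain_mask: np.ndarray, threshold: float = ISCHEMIC_TMAX_THRESHOLD_S) -> RegionMask:
    """Ischemic region: Tmax strictly above the hypoperfusion threshold."""
    return segment_threshold(tmax, brain_mask, "greater_than", threshold, region_kind="ischemic", threshold_units="s")


def segment_infarct(adc: ADCMap, brain_mask: np.ndarray, threshold: float = INFARCT_ADC_THRESHOLD) -> RegionMask:
    """Infarct core: ADC strictly below threshold, on valid ADC voxels only."""
    mask = np.asarray(brain_mask, dtype=bool) & adc.valid_mask
    out = segment_threshold(adc.adc, mask, "less_than", threshold, region_kind="infarct", threshold_units="mm^2/s")
    return out


@dataclass
class RegionParameters:
    """Mean of each perfusion map over a region; ``missing`` when empty."""

    means: dict = field(default_factory=dict)
    missing: bool = False


def region_mean_parameters(maps: dict, region: RegionMask | np.ndarray) -> RegionParameters:
    """Arithmetic mean of each perfusion map over the region's voxels.

    ``maps`` maps names (CBF, CBV, MTT, Tmax) to volumes.  An empty region
    yields NaN means with ``missing=True`` rather than an exception so a
    cohort summary can flag the subject.
    """
    mask = region.mask if isinstance(region, RegionMask) else np.asarray(region, dtype=bool)
    if mask.sum() == 0:
        return RegionParameters(means={name: float("nan") for name in maps}, missing=True)
    means = {}
    for name, vol in maps.items():
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"map {name!r} shape {vol.shape} != mask shape {mask.shape}")
        means[name] = float(vol[mask].mean())
    return RegionParameters(means=means, missing=False)
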