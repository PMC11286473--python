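"""Venous oxygen saturation (SvO2) grid procedure on susceptibility maps.

Hypoxic tissue is located from a quantitative susceptibility map (QSM, in
ppb) by comparing draining-vein susceptibility between mirrored grid units
of the two hemispheres:

1. the volume is brought upright: the brain centroid is translated to the
   in-plane volume centre and an in-plane rotation is applied so the
   midsagittal axis is vertical;
2. each hemisphere's per-slice bounding box is partitioned into a 10 x 10
   in-plane grid (one unit per axial slice in z);
3. vein voxels are ``90 ppb < chi < 300 ppb`` (strict on both ends: the
   lower bound extracts draining veins, the upper removes outlier points);
4. per unit, the mean vein susceptibility ``Xbar_vein`` is compared with
   the mirrored contralateral unit, assuming the contralateral hemisphere
   is healthy at ``SvO2_ref = 0.7``:

   ``dSvO2 = -(1 - SvO2_ref) * (Xbar_ref - Xbar_roi) / Xbar_ref``
   ``SvO2  = SvO2_ref - dSvO2``

5. affected-hemisphere units with ``SvO2 < 0.7`` (strict) are hypoxic.

Volumes are indexed ``(x, y, z)`` with x the left-right axis and z the
slice axis; "in-plane" means the (x, y) plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from perfrad.segmentation import RegionMask

HYPOXIC_SVO2_THRESHOLD: float = 0.7


@dataclass
class SvO2Params:
    """Constants of the SvO2 grid procedure.

    ``delta_chi_do`` (ppm, fully-oxygenated vs fully-deoxygenated blood
    susceptibility difference) and ``hct`` (venous hematocrit) appear in
    the physical vein-susceptibility model but cancel in the implemented
    ratio formula; they are carried for documentation only.
    """

    svo2_ref: float = 0.7          # assumed healthy contralateral SvO2
    delta_chi_do: float = 0.18     # ppm, documentation only
    hct: float = 0.42              # fraction, documentation only
    vein_low: float = 90.0         # ppb, lower vein threshold (strict >)
    vein_high: float = 300.0       # ppb, upper vein threshold (strict <)
    grid: tuple = (10, 10, 1)      # in-plane units (x, y), units per slice in z

    def __post_init__(self):
        if not (0.0 < self.svo2_ref < 1.0):
            raise ValueError(f"svo2_ref must be in (0, 1), got {self.svo2_ref}")
        if not (self.vein_low < self.vein_high):
            raise ValueError("vein_low must be below vein_high")
        gx, gy, gz = self.grid
        if gx < 1 or gy < 1 or gz < 1:
            raise ValueError("grid counts must be >= 1")
        if gz != 1:
            raise NotImplementedError("only one grid unit per axial slice (gz=1) is supported")


@dataclass
class RotationRecord:
    """In-plane alignment transform: shift then rotation, invertible."""

    angle_deg: float               # estimated midsagittal deviation angle
    shift_xy: tuple                # integer voxel shift applied (dx, dy)
    center_xy: tuple               # rotation centre (volume in-plane centre)

    def apply(self, volume: np.ndarray, order: int = 1) -> np.ndarray:
        """Align a volume (shift centroid to centre, then rotate upright)."""
        out = np.asarray(volume, dtype=float)
        dx, dy = self.shift_xy
        if dx or dy:
            out = ndimage.shift(out, (dx, dy, 0), order=0, cval=0.0)
        if self.angle_deg != 0.0:
            out = ndimage.rotate(out, -self.angle_deg, axes=(0, 1), reshape=False, order=order, cval=0.0)
        return out

    def apply_inverse(self, volume: np.ndarray, order: int = 0) -> np.ndarray:
        """Map an aligned-space volume (e.g. a mask) back to native space."""
        out = np.asarray(volume, dtype=float)
        if self.angle_deg != 0.0:
            out = ndimage.rotate(out, self.angle_deg, axes=(0, 1), reshape=False, order=order, cval=0.0)
        dx, dy = self.shift_xy
        if dx or dy:
            out = ndimage.shift(out, (-dx, -dy, 0), order=0, cval=0.0)
        return out


def _reflection_mismatch(mask: np.ndarray) -> int:
    """Voxel count differing between the mask and its left-right mirror."""
    return int(np.count_nonzero(mask != mask[::-1, :, :]))


def upright_align(
    chi: np.ndarray,
    brain_mask: np.ndarray,
    angle_range_deg: float = 20.0,
    angle_step_deg: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, RotationRecord]:
    """Bring a susceptibility volume upright for hemisphere mirroring.

    The brain centroid is translated (integer voxels) to the in-plane
    volume centre, then the deviation angle of the midsagittal axis is
    estimated by minimizing the left-right reflection mismatch of the
    brain mask over ``+/- angle_range_deg`` at ``angle_step_deg`` steps
    (ties broken toward the smallest magnitude), and the opposite
    rotation is applied.

    Returns ``(chi_aligned, mask_aligned, record)``.
    """
    chi = np.asarray(chi, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if chi.shape != brain_mask.shape:
        raise ValueError("chi and brain_mask shapes differ")
    n_vox = int(brain_mask.sum())
    nx, ny = brain_mask.shape[:2]
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    if n_vox <= 1:
        warnings.warn("degenerate brain mask; skipping upright alignment")
        rec = RotationRecord(angle_deg=0.0, shift_xy=(0, 0), center_xy=center)
        return chi.copy(), brain_mask.copy(), rec

    cx, cy = (np.asarray(np.nonzero(brain_mask))[:2].mean(axis=1))
    dx = int(round(center[0] - cx))
    dy = int(round(center[1] - cy))

    mask_shifted = brain_mask
    if dx or dy:
        mask_shifted = ndimage.shift(brain_mask.astype(np.uint8), (dx, dy, 0), order=0, cval=0).astype(bool)

    angles = np.arange(-angle_range_deg, angle_range_deg + 1e-9, angle_step_deg)
    angles = angles[np.argsort(np.abs(angles), kind="stable")]
    best_angle, best_cost = 0.0, None
    for a in angles:
        if a == 0.0:
            rotated = mask_shifted
        else:
            rotated = ndimage.rotate(mask_shifted.astype(np.uint8), -a, axes=(0, 1), reshape=False, order=0, cval=0).astype(bool)
        cost = _reflection_mismatch(rotated)
        if best_cost is None or cost < best_cost:
            best_cost, best_angle = cost, float(a)

    rec = RotationRecord(angle_deg=best_angle, shift_xy=(dx, dy), center_xy=center)
    chi_aligned = rec.apply(chi, order=1)
    mask_aligned = rec.apply(brain_mask.astype(np.uint8), order=0) > 0.5
    return chi_aligned, mask_aligned, rec


@dataclass(frozen=True)
class GridUnit:
    """Half-open voxel extent of one grid unit on one axial slice.

    ``i`` indexes the left-right axis from medial (next to the midline)
    to lateral in both hemispheres, so unit (i, j) mirrors unit (i, j) of
    the contralateral hemisphere; ``j`` indexes y ascending.
    """

    hemisphere: str  # 'L' | 'R'
    z: int
    i: int
    j: int
    x_lo: int
    x_hi: int
    y_lo: int
    y_hi: int

    def voxel_mask(self, shape: tuple) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.x_lo:self.x_hi, self.y_lo:self.y_hi, self.z] = True
        return m


@dataclass
class GridPartition:
    """All grid units of both hemispheres plus the midline index."""

    units: list
    midline_x: int
    shape: tuple
    grid: tuple

    def lookup(self, hemisphere: str, z: int, i: int, j: int) -> GridUnit | None:
        return self._index.get((hemisphere, z, i, j))

    def __post_init__(self):
        self._index = {(u.hemisphere, u.z, u.i, u.j): u for u in self.units}


def _axis_edges(lo: int, hi: int, n: int, remainder_first: bool = False) -> list:
    """Split [lo, hi) into n intervals; remainder widens one end interval.

    Remainder voxels go to the last interval by default, or to the first
    when ``remainder_first`` — used so that the widened x-interval sits at
    the lateral end of both hemispheres and mirrored units stay congruent.
    """
    width = hi - lo
    base = width // n
    rem = width - base * n
    widths = [base] * n
    widths[0 if remainder_first else -1] += rem
    edges = [lo]
    for w in widths:
        edges.append(edges[-1] + w)
    return edges


def partition_hemisphere_grid(
    brain_mask: np.ndarray,
    midline_x: int | None = None,
    grid: tuple = (10, 10, 1),
) -> GridPartition:
    """Partition each hemisphere's per-slice bounding box into grid units.

    The midline is the vertical plane through the brain-mask centroid
    (assumed upright-aligned); the left hemisphere is ``x < midline_x``.
    Per axial slice, the bounding box of the in-hemisphere brain mask is
    split into ``grid[0] x grid[1]`` units with remainder voxels in the
    last unit per axis.  Slices where a hemisphere has no brain voxels
    get no units there.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    gx, gy, gz = grid
    if gz != 1:
        raise NotImplementedError("only gz=1 (one unit per slice) is supported")
    if midline_x is None:
        if not brain_mask.any():
            raise ValueError("empty brain mask")
        midline_x = int(round(np.nonzero(brain_mask)[0].mean()))
    units = []
    nz = brain_mask.shape[2]
    for z in range(nz):
        sl = brain_mask[:, :, z]
        for hemi in ("L", "R"):
            hm = sl.copy()
            if hemi == "L":
                hm[midline_x:, :] = False
            else:
                hm[:midline_x, :] = False
            if not hm.any():
                continue
            xs, ys = np.nonzero(hm)
            x_lo, x_hi = int(xs.min()), int(xs.max()) + 1
            y_lo, y_hi = int(ys.min()), int(ys.max()) + 1
            x_edges = _axis_edges(x_lo, x_hi, gx, remainder_first=(hemi == "L"))
            y_edges = _axis_edges(y_lo, y_hi, gy)
            for ix in range(gx):
                for j in range(gy):
                    # medial-to-lateral i: left hemisphere counts x descending
                    i = (gx - 1 - ix) if hemi == "L" else ix
                    units.append(GridUnit(
                        hemisphere=hemi, z=z, i=i, j=j,
                        x_lo=x_edges[ix], x_hi=x_edges[ix + 1],
                        y_lo=y_edges[j], y_hi=y_edges[j + 1],
                    ))
    return GridPartition(units=units, midline_x=midline_x, shape=brain_mask.shape, grid=grid)


@dataclass
class SvO2Grid:
    """Per-unit vein susceptibility and SvO2 table plus the partition.

    ``table`` columns: hemisphere, z, i, j, n_vein, xbar_vein, delta_svo2,
    svo2, is_hypoxic.  ``xbar_vein`` is NaN where the unit has no vein
    voxels; ``svo2`` is NaN wherever either the unit's or its mirror's
    vein mean is missing or the reference mean is zero.
    """

    table: pd.DataFrame
    partition: GridPartition
    params: SvO2Params = field(default_factory=SvO2Params)


def delta_svo2(xbar_ref: float, xbar_roi: float, svo2_ref: float = 0.7) -> float:
    """Change in venous oxygen saturation of a unit vs its mirror.

    ``dSvO2 = -(1 - SvO2_ref) * (Xbar_ref - Xbar_roi) / Xbar_ref``; the
    blood-susceptibility constants cancel in this ratio form.
    """
    if xbar_ref == 0:
        raise ZeroDivisionError("reference vein susceptibility is zero")
    return -(1.0 - svo2_ref) * (xbar_ref - xbar_roi) / xbar_ref


def compute_unit_svo2(
    chi: np.ndarray,
    partition: GridPartition,
    params: SvO2Params | None = None,
) -> SvO2Grid:
    """Compute per-unit mean vein susceptibility and SvO2.

    Vein voxels satisfy ``vein_low < chi < vein_high`` strictly.  Each
    unit's SvO2 uses the mirrored contralateral unit as reference;
    units with a missing or zero reference mean get NaN SvO2 (never
    infinity).  ``is_hypoxic`` flags defined SvO2 strictly below 0.7.
    """
    params = params or SvO2Params()
    chi = np.asarray(chi, dtype=float)
    if chi.shape != partition.shape:
        raise ValueError("chi shape differs from partition shape")
    vein = (chi > params.vein_low) & (chi < params.vein_high)

    rows = []
    xbar = {}
    for u in partition.units:
        block_v = vein[u.x_lo:u.x_hi, u.y_lo:u.y_hi, u.z]
        n = int(block_v.sum())
        if n == 0:
            xbar[(u.hemisphere, u.z, u.i, u.j)] = (np.nan, 0)
        else:
            block_c = chi[u.x_lo:u.x_hi, u.y_lo:u.y_hi, u.z]
            # sort before averaging: the mean is then independent of voxel
            # visit order, so mirrored units with equal values agree exactly
            xbar[(u.hemisphere, u.z, u.i, u.j)] = (float(np.sort(block_c[block_v]).mean()), n)

    for u in partition.units:
        key = (u.hemisphere, u.z, u.i, u.j)
        mirror = ("R" if u.hemisphere == "L" else "L", u.z, u.i, u.j)
        x_roi, n = xbar[key]
        x_ref = xbar.get(mirror, (np.nan, 0))[0]
        if np.isnan(x_roi) or np.isnan(x_ref) or x_ref == 0.0:
            d = np.nan
            s = np.nan
        else:
            d = delta_svo2(x_ref, x_roi, params.svo2_ref)
            s = params.svo2_ref - d
        rows.append({
            "hemisphere": u.hemisphere, "z": u.z, "i": u.i, "j": u.j,
            "n_vein": n, "xbar_vein": x_roi, "delta_svo2": d, "svo2": s,
            "is_hypoxic": bool(not np.isnan(s) and s < HYPOXIC_SVO2_THRESHOLD),
        })
    return SvO2Grid(table=pd.DataFrame(rows), partition=partition, params=params)


def segment_hypoxic(
    svo2_grid: SvO2Grid,
    brain_mask: np.ndarray,
    affected_hemisphere: str,
) -> RegionMask:
    """Hypoxic region: affected-hemisphere units with SvO2 < 0.7 (strict).

    The mask is the union of the flagged units' voxel extents intersected
    with the brain mask; units with undefined SvO2 are excluded.  An
    empty mask is a valid outcome.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    mask = np.zeros(brain_mask.shape, dtype=bool)
    t = svo2_grid.table
    flagged = t[(t.hemisphere == affected_hemisphere) & t.is_hypoxic]
    for _, r in flagged.iterrows():
        u = svo2_grid.partition.lookup(r.hemisphere, int(r.z), int(r.i), int(r.j))
        mask[u.x_lo:u.x_hi, u.y_lo:u.y_hi, int(r.z)] = True
    mask &= brain_mask
    return RegionMask(mask=mask, region_kind="hypoxic", threshold_used=HYPOXIC_SVO2_THRESHOLD, threshold_units="SvO2 fraction")


def affected_hemisphere_of(lesion_mask: np.ndarray, midline_x: int) -> str:
    """Hemisphere ('L'/'R') containing the lesion-mask centroid."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    cx = np.nonzero(lesion_mask)[0].mean()
    return "L" if cx < midline_x else "R"
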