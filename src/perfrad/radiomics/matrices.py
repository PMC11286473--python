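"""Gray-level texture matrices built from first principles.

All five families operate on a discretized image (levels 1..Ng inside the
mask, 0 outside):

* GLCM  — symmetric co-occurrence counts at Chebyshev distance 1 over the
  13 unique 3D directions (one matrix per direction);
* GLRLM — run-length counts per direction (runs of equal level along the
  direction);
* GLSZM — 26-connected zone sizes per level (direction-free);
* GLDM  — per voxel, the number of 26-neighbours with the same level
  (dependence); matrix column j counts dependence size j+1;
* NGTDM — per level: voxel count ``n_i`` and summed absolute deviation
  ``s_i`` of the level from the mean level of its in-mask 26-neighbours
  (voxels with no in-mask neighbour are excluded).

Everything is vectorized numpy; independent brute-force enumerations live
in the test suite as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from perfrad.radiomics.discretize import DiscretizedImage


def _unique_directions():
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if dx > 0 or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0):
                    dirs.append((dx, dy, dz))
    return tuple(dirs)


#: 13 unique direction offsets at Chebyshev distance 1 in 3D.
UNIQUE_DIRECTIONS_3D = _unique_directions()

#: All 26 neighbour offsets.
NEIGHBOURS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass
class TextureMatrix:
    """A texture matrix (or per-direction stack) with its convention.

    GLCM: ``matrix`` has shape (n_directions, Ng, Ng), symmetric counts.
    GLRLM: (n_directions, Ng, max_run_length) run counts.
    GLSZM: (Ng, max_zone_size) zone counts.
    GLDM: (Ng, max_dependence) counts; column j = dependence size j+1.
    NGTDM: (2, Ng) stacking ``n_i`` and ``s_i``.
    """

    family: str
    matrix: np.ndarray
    n_levels: int
    n_voxels: int
    aggregation: str = "averaged"


def _pair_slices(shape, off):
    """Slices (sl_a, sl_b) so A[sl_a][k] and A[sl_b][k] are voxels v, v+off."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, off):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def _shift(arr: np.ndarray, off) -> np.ndarray:
    """out(v) = arr(v + off), zero-filled at the borders."""
    out = np.zeros_like(arr)
    sl_a, sl_b = _pair_slices(arr.shape, off)
    out[sl_a] = arr[sl_b]
    return out


def _resolve(disc: DiscretizedImage, mask):
    levels = disc.levels
    in_mask = disc.mask if mask is None else (np.asarray(mask, dtype=bool) & disc.mask)
    if not in_mask.any():
        raise ValueError("empty mask")
    return levels, in_mask, disc.n_levels


def glcm_matrix(disc: DiscretizedImage, mask=None, directions=UNIQUE_DIRECTIONS_3D) -> TextureMatrix:
    levels, in_mask, ng = _resolve(disc, mask)
    stack = np.zeros((len(directions), ng, ng), dtype=np.int64)
    for k, off in enumerate(directions):
        sl_a, sl_b = _pair_slices(levels.shape, off)
        la, lb = levels[sl_a], levels[sl_b]
        valid = in_mask[sl_a] & in_mask[sl_b]
        a = la[valid] - 1
        b = lb[valid] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        stack[k] = counts + counts.T  # symmetric: count (a,b) and (b,a)
    return TextureMatrix("GLCM", stack, ng, int(in_mask.sum()))


def glrlm_matrix(disc: DiscretizedImage, mask=None, directions=UNIQUE_DIRECTIONS_3D) -> TextureMatrix:
    levels, in_mask, ng = _resolve(disc, mask)
    max_len = max(levels.shape)
    stack = np.zeros((len(directions), ng, max_len), dtype=np.int64)
    lv = np.where(in_mask, levels, 0)
    for k, off in enumerate(directions):
        nxt_lv = _shift(lv, off)
        same = (lv > 0) & (lv == nxt_lv)  # v and v+off continue a run
        # run length from each voxel forward
        run_len = (lv > 0).astype(np.int64)
        chain = same.copy()
        shifted = same.copy()
        while chain.any():
            run_len += chain
            shifted = _shift(shifted, off)
            chain &= shifted
        neg = tuple(-d for d in off)
        same_prev = _shift(same, neg)  # True if v-off, v continue a run
        start = (lv > 0) & ~same_prev
        g = lv[start] - 1
        r = run_len[start] - 1
        stack[k] = np.bincount(g * max_len + r, minlength=ng * max_len).reshape(ng, max_len)
    # trim unused long-run columns (max realized run across directions)
    used = np.nonzero(stack.sum(axis=(0, 1)))[0]
    stack = stack[:, :, : used[-1] + 1]
    return TextureMatrix("GLRLM", stack, ng, int(in_mask.sum()))


def glszm_matrix(disc: DiscretizedImage, mask=None) -> TextureMatrix:
    levels, in_mask, ng = _resolve(disc, mask)
    lv = np.where(in_mask, levels, 0)
    structure = np.ones((3, 3, 3), dtype=int)
    zones = []  # (level, size)
    for level in range(1, ng + 1):
        binary = lv == level
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
    max_size = max(s for _, s in zones)
    out = np.zeros((ng, max_size), dtype=np.int64)
    for level, s in zones:
        out[level - 1, s - 1] += 1
    return TextureMatrix("GLSZM", out, ng, int(in_mask.sum()))


def gldm_matrix(disc: DiscretizedImage, mask=None, alpha: int = 0) -> TextureMatrix:
    levels, in_mask, ng = _resolve(disc, mask)
    lv = np.where(in_mask, levels, 0)
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in NEIGHBOURS_26:
        nb = _shift(lv, off)
        dep += (nb > 0) & (np.abs(nb - lv) <= alpha)
    g = lv[in_mask] - 1
    d = dep[in_mask]
    max_dep = int(d.max()) + 1
    out = np.bincount(g * max_dep + d, minlength=ng * max_dep).reshape(ng, max_dep)
    return TextureMatrix("GLDM", out, ng, int(in_mask.sum()))


def ngtdm_matrix(disc: DiscretizedImage, mask=None) -> TextureMatrix:
    levels, in_mask, ng = _resolve(disc, mask)
    lv = np.where(in_mask, levels, 0).astype(float)
    inm = in_mask.astype(float)
    sum_nb = np.zeros(lv.shape)
    cnt_nb = np.zeros(lv.shape)
    for off in NEIGHBOURS_26:
        sum_nb += _shift(lv, off)
        cnt_nb += _shift(inm, off)
    valid = in_mask & (cnt_nb > 0)
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=float)
    g = levels[valid] - 1
    mean_nb = sum_nb[valid] / cnt_nb[valid]
    dev = np.abs(levels[valid] - mean_nb)
    np.add.at(n_i, g, 1)
    np.add.at(s_i, g, dev)
    return TextureMatrix("NGTDM", np.stack([n_i.astype(float), s_i]), ng, int(in_mask.sum()))


_BUILDERS = {
    "GLCM": glcm_matrix,
    "GLRLM": glrlm_matrix,
    "GLSZM": glszm_matrix,
    "GLDM": gldm_matrix,
    "NGTDM": ngtdm_matrix,
}


def build_texture_matrix(disc: DiscretizedImage, family: str, mask=None, **kwargs) -> TextureMatrix:
    try:
        builder = _BUILDERS[family.upper()]
    except KeyError:
        raise ValueError(f"unknown texture family {family!r}; expected one of {sorted(_BUILDERS)}")
    return builder(disc, mask=mask, **kwargs)
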