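"""Synthetic two-class stroke cohort phantoms.

Each subject phantom is a set of co-registered volumes on one grid: four
perfusion parameter maps (CBF mL/100g/min, CBV mL/100g, MTT s, Tmax s), a
DWI pair (b=0 and b=1000 s/mm^2) synthesized by inverting the ADC
log-ratio relation from a ground-truth ADC field, a susceptibility map
(ppb) carrying mirrored vein-like tubes, a brain mask, ground-truth
ischemic / infarct / hypoxic masks, and a class label (good / poor
neurological function, i.e. NIHSS 0-4 vs 5-42).

Geometry is a modeling choice (ellipsoidal unilateral lesions, random-walk
vein tubes); what is anchored to the clinical study being emulated are the
distributional targets: per (region, map, class) means and SDs of the
subject-level regional means, defaulting to the published two-class
cohort statistics (``TABLE_CLASS_EFFECTS``).

Construction guarantees, independent of noise level:

* truth masks are nested/disjoint as designed (infarct inside ischemic,
  hypoxic units disjoint from the lesion) and confined to one hemisphere;
* the ground-truth infarct mask coincides voxelwise with thresholding the
  ADC map recomputed from the generated DWI pair (ADC is clipped strictly
  below 620e-6 mm^2/s inside the core and strictly above outside);
* identical seeds give bit-identical phantoms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from perfrad.segmentation import PERFUSION_MAPS, RegionMask, region_mean_parameters
from perfrad.svo2 import partition_hemisphere_grid

GOOD, POOR = "good", "poor"
REGIONS = ("ischemic", "infarct", "hypoxic")

#: Default per-(region, map, class) targets: (mean, SD) of subject-level
#: regional means, from the published 45+45 patient cohort.
TABLE_CLASS_EFFECTS = {
    "ischemic": {
        "CBF": {GOOD: (28.05, 11.90), POOR: (20.34, 9.47)},
        "CBV": {GOOD: (3.83, 1.44), POOR: (3.49, 1.11)},
        "MTT": {GOOD: (9.42, 3.27), POOR: (13.67, 5.31)},
        "Tmax": {GOOD: (6.24, 4.49), POOR: (12.18, 6.28)},
    },
    "infarct": {
        "CBF": {GOOD: (28.22, 16.56), POOR: (17.81, 10.81)},
        "CBV": {GOOD: (3.54, 1.59), POOR: (2.88, 1.31)},
        "MTT": {GOOD: (9.53, 4.49), POOR: (14.73, 5.83)},
        "Tmax": {GOOD: (5.80, 5.33), POOR: (13.99, 8.39)},
    },
    "hypoxic": {
        "CBF": {GOOD: (58.54, 18.50), POOR: (47.36, 18.83)},
        "CBV": {GOOD: (7.91, 2.09), POOR: (6.94, 2.11)},
        "MTT": {GOOD: (8.13, 1.19), POOR: (9.51, 2.22)},
        "Tmax": {GOOD: (3.65, 0.97), POOR: (5.32, 2.43)},
    },
}

#: Normal-appearing tissue values per map (background of the phantom).
BACKGROUND_MEANS = {"CBF": 45.0, "CBV": 4.0, "MTT": 5.0, "Tmax": 2.0}

#: Voxel-level noise SD per map (map units).
DEFAULT_NOISE_SD = {"CBF": 2.0, "CBV": 0.3, "MTT": 0.5, "Tmax": 0.5}


@dataclass
class CohortConfig:
    """Cohort generation settings; defaults are the emulated study conditions."""

    n_good: int = 45
    n_poor: int = 45
    volume_shape: tuple = (48, 48, 14)
    voxel_spacing: tuple = (4.0, 4.0, 5.0)  # mm
    lesion_radius_range: tuple = (4.0, 7.0)  # voxels, ischemic semi-axes
    infarct_radius_fraction: float = 0.55
    class_effects: dict = field(default_factory=lambda: TABLE_CLASS_EFFECTS)
    background_means: dict = field(default_factory=lambda: dict(BACKGROUND_MEANS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    boundary_taper_sigma: float = 1.0  # voxels; 0 = hard lesion edges
    vein_chi_range: tuple = (120.0, 200.0)  # ppb
    chi_noise_sd: float = 5.0  # ppb, on vein voxels
    hypoxic_chi_boost: float = 80.0  # ppb added to veins of hypoxic units
    n_hypoxic_units: int = 6
    n_veins: int = 40  # random-walk tubes per hemisphere
    adc_background: float = 800e-6  # mm^2/s
    adc_infarct: tuple = (450e-6, 60e-6)  # (mean, SD) of core ADC
    adc_noise_sd: float = 15e-6
    dwi_b: float = 1000.0  # s/mm^2
    dwi_s0: float = 1000.0
    grid: tuple = (10, 10, 1)
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 0 or self.n_poor < 0:
            raise ValueError("cohort sizes must be non-negative")
        for region, per_map in self.class_effects.items():
            for name, per_class in per_map.items():
                for label, (_, sd) in per_class.items():
                    if sd < 0:
                        raise ValueError(f"negative SD for {region}/{name}/{label}")
        r_max = max(self.lesion_radius_range)
        half_x = self.volume_shape[0] // 2
        if r_max * 2 + 2 > half_x:
            raise ValueError("lesion radius range does not fit inside one hemisphere")


@dataclass
class SubjectPhantom:
    """One subject's co-registered volume set with ground truth."""

    subject_id: str
    label: str
    maps: dict                 # CBF, CBV, MTT, Tmax volumes
    dwi_b0: np.ndarray
    dwi_b1000: np.ndarray
    chi: np.ndarray            # susceptibility, ppb
    brain_mask: np.ndarray
    truth_masks: dict          # ischemic / infarct / hypoxic binary volumes
    voxel_spacing: tuple
    seed: int
    affected_hemisphere: str   # 'L' | 'R'

    def truth_region(self, kind: str) -> RegionMask:
        return RegionMask(mask=self.truth_masks[kind], region_kind=kind, threshold_used=float("nan"))


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _correlated_noise(rng, shape, sd, sigma=1.0) -> np.ndarray:
    """Zero-mean spatially correlated Gaussian field with voxel SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(shape)


@lru_cache(maxsize=4096)
def _truncation_corrected_mean(target: float, sd: float) -> float:
    """Mean mu such that E[max(N(mu, sd), 0)] equals ``target``.

    Subject-level region values are floored at zero (perfusion maps are
    non-negative); drawing from the corrected normal keeps the realized
    across-subject mean on target despite the floor.
    """
    if sd == 0 or target <= 0:
        return target
    if target / sd > 8:  # floor never binds in practice
        return target

    sqrt2 = math.sqrt(2.0)
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)

    def clipped_mean(mu):
        z = mu / sd
        return mu * 0.5 * (1.0 + math.erf(z / sqrt2)) + sd * inv_sqrt2pi * math.exp(-0.5 * z * z)

    lo, hi = target - 5 * sd, target + sd
    return float(brentq(lambda mu: clipped_mean(mu) - target, lo, hi, xtol=1e-10))


def _taper_weight(mask: np.ndarray, sigma: float) -> np.ndarray:
    """1 inside the mask, Gaussian decay outside (never dilutes the inside)."""
    if sigma <= 0:
        return mask.astype(float)
    smooth = ndimage.gaussian_filter(mask.astype(float), sigma)
    return np.maximum(mask.astype(float), smooth)


def _random_walk_veins(rng, brain_mask, x_min, x_max, n_veins, n_steps=20):
    """Vein voxel mask from random-walk tubes confined to one hemisphere.

    Each tube marks the walk path, thickened by its 6-neighbourhood
    (about 1 voxel radius); walks stay inside the brain mask and in
    ``x_min..x_max``.
    """
    shape = brain_mask.shape
    allowed = brain_mask.copy()
    allowed[:x_min] = False
    allowed[x_max + 1:] = False
    path = np.zeros(shape, dtype=bool)
    candidates = np.argwhere(allowed)
    if len(candidates) == 0:
        return path
    steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for _ in range(n_veins):
        pos = candidates[rng.integers(len(candidates))].copy()
        moves = steps[rng.integers(6, size=n_steps)]
        for step in moves:
            path[tuple(pos)] = True
            q = pos + step
            if (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2]
                    and allowed[tuple(q)]):
                pos = q
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    vein = ndimage.binary_dilation(path, structure=struct) & allowed
    return vein


def _brain_mask(shape) -> np.ndarray:
    nx, ny, nz = shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    radii = (0.44 * nx, 0.46 * ny, 0.48 * nz)
    return _ellipsoid(shape, center, radii)


@lru_cache(maxsize=8)
def _phantom_geometry(shape: tuple, grid: tuple):
    """Shared per-shape geometry: brain mask, grid partition, unit brain counts.

    The phantom head is identical across subjects, so this is computed once.
    """
    brain = _brain_mask(shape)
    partition = partition_hemisphere_grid(brain, grid=grid)
    brain_counts = {}
    for u in partition.units:
        brain_counts[(u.hemisphere, u.z, u.i, u.j)] = int(
            brain[u.x_lo:u.x_hi, u.y_lo:u.y_hi, u.z].sum()
        )
    return brain, partition, brain_counts


def mirror_lr(mask: np.ndarray) -> np.ndarray:
    """Reflect a volume across the left-right axis (x -> nx-1-x)."""
    return np.asarray(mask)[::-1, :, :].copy()


def _draw_region_value(rng, config, region, name, label) -> float:
    mean, sd = config.class_effects[region][name][label]
    mu = _truncation_corrected_mean(mean, sd)
    return max(float(rng.normal(mu, sd)) if sd > 0 else mu, 0.0)


def generate_subject(config: CohortConfig, label: str, seed: int, subject_id: str | None = None) -> SubjectPhantom:
    """Generate one subject phantom.

    Regional map values are assigned so that the mean over each truth
    region matches the subject-level draw exactly before voxel noise: the
    infarct core gets its own value and the ischemic rim is compensated so
    the whole-ischemic mean stays on target.  The affected hemisphere is
    chosen at random; the contralateral side remains lesion-free.
    """
    if label not in (GOOD, POOR):
        raise ValueError(f"label must be '{GOOD}' or '{POOR}', got {label!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(config.volume_shape)
    nx, ny, nz = shape
    brain, partition, brain_counts = _phantom_geometry(shape, tuple(config.grid))
    mid = partition.midline_x

    affected = "L" if rng.random() < 0.5 else "R"

    # --- lesion geometry: ischemic ellipsoid with concentric infarct core
    r_lo, r_hi = config.lesion_radius_range
    radii = rng.uniform(r_lo, r_hi, size=3)
    radii[2] = max(1.5, radii[2] * nz / nx)  # fewer slices than in-plane voxels
    margin = 2
    if affected == "L":
        x_lo, x_hi = margin + radii[0], mid - 1 - radii[0]
    else:
        x_lo, x_hi = mid + 1 + radii[0], nx - 1 - margin - radii[0]
    if x_hi <= x_lo:
        raise ValueError("lesion cannot fit inside one hemisphere of the volume")
    center = (
        rng.uniform(x_lo, x_hi),
        rng.uniform(ny * 0.35, ny * 0.65),
        rng.uniform(nz * 0.4, nz * 0.6),
    )
    ischemic = _ellipsoid(shape, center, radii) & brain
    infarct = _ellipsoid(shape, center, np.maximum(radii * config.infarct_radius_fraction, 1.0)) & brain
    infarct &= ischemic
    if ischemic.sum() < 8 or infarct.sum() < 1:
        raise ValueError("degenerate lesion; enlarge lesion_radius_range")

    # --- veins: mirrored random-walk tubes, then per-voxel chi values
    vein_r = _random_walk_veins(rng, brain, mid + 1, nx - 2, config.n_veins)
    chi = np.zeros(shape)
    lo, hi = config.vein_chi_range
    chi[vein_r] = rng.uniform(lo, hi, size=int(vein_r.sum()))
    chi = np.maximum(chi, mirror_lr(chi))  # exact mirrored copy on the left
    vein = vein_r | mirror_lr(vein_r)
    if config.chi_noise_sd > 0:
        chi[vein] += rng.normal(0.0, config.chi_noise_sd, size=int(vein.sum()))

    # --- hypoxic units: affected-hemisphere grid units with veins on both
    # sides, disjoint from the lesion
    candidates = []
    for u in partition.units:
        if u.hemisphere != affected:
            continue
        if brain_counts[(u.hemisphere, u.z, u.i, u.j)] < 4:
            continue
        ext = np.s_[u.x_lo:u.x_hi, u.y_lo:u.y_hi, u.z]
        if not vein[ext].any() or ischemic[ext].any():
            continue
        m = partition.lookup("R" if affected == "L" else "L", u.z, u.i, u.j)
        if m is None or not vein[m.x_lo:m.x_hi, m.y_lo:m.y_hi, m.z].any():
            continue
        candidates.append(u)
    n_units = min(config.n_hypoxic_units, len(candidates))
    chosen = [candidates[k] for k in rng.choice(len(candidates), size=n_units, replace=False)] if n_units else []
    hypoxic = np.zeros(shape, dtype=bool)
    for u in chosen:
        ext = np.s_[u.x_lo:u.x_hi, u.y_lo:u.y_hi, u.z]
        hypoxic[ext] |= brain[ext]
        block = chi[ext]
        block[vein[ext]] += config.hypoxic_chi_boost
        chi[ext] = block

    # --- perfusion maps: background + region values + truncated noise
    maps = {}
    n_isch, n_inf = int(ischemic.sum()), int(infarct.sum())
    rim = ischemic & ~infarct
    n_rim = int(rim.sum())
    for name in PERFUSION_MAPS:
        bg = config.background_means[name]
        m_isch = _draw_region_value(rng, config, "ischemic", name, label)
        m_inf = _draw_region_value(rng, config, "infarct", name, label)
        m_hyp = _draw_region_value(rng, config, "hypoxic", name, label)
        # rim value compensated so the whole-ischemic mean hits its draw
        c = (n_isch * m_isch - n_inf * m_inf) / n_rim if n_rim else m_isch
        c = max(c, 0.0)
        vol = np.full(shape, bg)
        w = _taper_weight(ischemic, config.boundary_taper_sigma)
        vol = bg + (c - bg) * w
        vol[infarct] = m_inf
        w_h = _taper_weight(hypoxic, config.boundary_taper_sigma)
        vol = vol + (m_hyp - bg) * w_h * ~ischemic
        vol[hypoxic] = m_hyp
        sd = config.noise_sd.get(name, 0.0)
        if sd > 0:
            vol = vol + _correlated_noise(rng, shape, sd)
        vol = np.clip(vol, 0.0, None)
        vol[~brain] = 0.0
        maps[name] = vol

    # --- ADC field and DWI pair (strictly consistent with the 620e-6 rule)
    adc = np.full(shape, config.adc_background)
    if config.adc_noise_sd > 0:
        adc = adc + _correlated_noise(rng, shape, config.adc_noise_sd)
    adc = np.clip(adc, 640e-6, None)
    mu_adc, sd_adc = config.adc_infarct
    core = float(rng.normal(mu_adc, sd_adc)) if sd_adc > 0 else mu_adc
    core_field = core + _correlated_noise(rng, shape, config.adc_noise_sd)
    adc[infarct] = np.clip(core_field[infarct], 50e-6, 615e-6)
    dwi_b0 = np.full(shape, config.dwi_s0)
    dwi_b0 = np.clip(dwi_b0 + _correlated_noise(rng, shape, config.dwi_s0 * 0.02), 1.0, None)
    dwi_b1000 = dwi_b0 * np.exp(-config.dwi_b * adc)
    dwi_b0[~brain] = 0.0
    dwi_b1000[~brain] = 0.0

    return SubjectPhantom(
        subject_id=subject_id or f"sub-{seed}",
        label=label,
        maps=maps,
        dwi_b0=dwi_b0,
        dwi_b1000=dwi_b1000,
        chi=chi,
        brain_mask=brain.copy(),  # geometry is cached per shape; hand out a copy
        truth_masks={"ischemic": ischemic, "infarct": infarct, "hypoxic": hypoxic},
        voxel_spacing=config.voxel_spacing,
        seed=seed,
        affected_hemisphere=affected,
    )


def generate_cohort(config: CohortConfig) -> list[SubjectPhantom]:
    """Generate the configured two-class cohort.

    Per-subject seeds are ``config.seed + index`` so a cohort is
    reproducible while subjects remain distinct.
    """
    n = config.n_good + config.n_poor
    if n < 1:
        raise ValueError("zero subjects requested")
    labels = [GOOD] * config.n_good + [POOR] * config.n_poor
    cohort = []
    for idx, label in enumerate(labels):
        cohort.append(generate_subject(config, label, seed=config.seed + idx, subject_id=f"sub-{idx:03d}"))
    return cohort


def summarize_cohort(cohort: list[SubjectPhantom], regions=REGIONS):
    """Per-(region, map, class) mean and sample SD of subject regional means.

    Subjects with an empty region are counted in ``n_missing`` and
    excluded from the statistics rather than contributing zeros.
    """
    import pandas as pd

    records = {}
    for subj in cohort:
        for region in regions:
            params = region_mean_parameters(subj.maps, subj.truth_masks[region])
            for name in PERFUSION_MAPS:
                key = (region, name, subj.label)
                records.setdefault(key, {"values": [], "missing": 0})
                if params.missing:
                    records[key]["missing"] += 1
                else:
                    records[key]["values"].append(params.means[name])
    rows = []
    for (region, name, label), rec in sorted(records.items()):
        vals = np.array(rec["values"])
        rows.append({
            "region": region, "map": name, "class": label,
            "n": len(vals), "n_missing": rec["missing"],
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) == 1 else float("nan")),
        })
    return pd.DataFrame(rows)


# --- NIfTI / manifest I/O -------------------------------------------------

def save_subject(subject: SubjectPhantom, out_dir: str | Path) -> dict:
    """Write a subject's volumes as NIfTI plus a JSON sidecar; returns paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(subject.voxel_spacing) + [1.0])
    paths = {}

    def _save(name, vol, dtype=np.float32):
        p = out_dir / f"{subject.subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=dtype), affine), p)
        paths[name] = str(p)

    for name, vol in subject.maps.items():
        _save(name, vol)
    _save("dwi_b0", subject.dwi_b0)
    _save("dwi_b1000", subject.dwi_b1000)
    _save("chi", subject.chi)
    _save("brain_mask", subject.brain_mask, np.uint8)
    for kind, mask in subject.truth_masks.items():
        _save(f"mask_{kind}", mask, np.uint8)
    sidecar = {
        "subject_id": subject.subject_id,
        "label": subject.label,
        "seed": subject.seed,
        "affected_hemisphere": subject.affected_hemisphere,
        "voxel_spacing": list(subject.voxel_spacing),
        "paths": paths,
    }
    sidecar_path = out_dir / f"{subject.subject_id}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    sidecar["sidecar"] = str(sidecar_path)
    return sidecar


def load_subject(sidecar_path: str | Path) -> SubjectPhantom:
    """Load a subject previously written by :func:`save_subject`."""
    import nibabel as nib

    meta = json.loads(Path(sidecar_path).read_text())
    vol = {k: np.asarray(nib.load(p).dataobj) for k, p in meta["paths"].items()}
    return SubjectPhantom(
        subject_id=meta["subject_id"],
        label=meta["label"],
        maps={name: vol[name].astype(float) for name in PERFUSION_MAPS},
        dwi_b0=vol["dwi_b0"].astype(float),
        dwi_b1000=vol["dwi_b1000"].astype(float),
        chi=vol["chi"].astype(float),
        brain_mask=vol["brain_mask"].astype(bool),
        truth_masks={k: vol[f"mask_{k}"].astype(bool) for k in REGIONS},
        voxel_spacing=tuple(meta["voxel_spacing"]),
        seed=meta["seed"],
        affected_hemisphere=meta["affected_hemisphere"],
    )
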