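"""Feature-vector assembly over maps, filters and feature classes.

Feature names follow the schema ``region__map__filter__class__feature``,
e.g. ``ischemic__Tmax__log-sigma-3__glszm__ZoneEntropy``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from perfrad.radiomics.discretize import discretize
from perfrad.radiomics.filters import FilterSpec, apply_filter, default_filter_bank
from perfrad.radiomics.firstorder import first_order_features
from perfrad.radiomics.matrices import build_texture_matrix
from perfrad.radiomics.texture import texture_features

FEATURE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


class RegionTooSmallError(ValueError):
    """Region below the minimum voxel count; features are not fabricated."""


def _bbox(mask: np.ndarray, margin: int = 1):
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(a.min()) - margin, 0), min(int(a.max()) + margin + 1, n))
        for a, n in zip(idx, mask.shape)
    )


def extract_features_single(
    image: np.ndarray,
    mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    classes=FEATURE_CLASSES,
    bin_width: float = 25.0,
    scheme: str = "fixed_bin_width",
    bin_count: int = 32,
) -> dict:
    """All requested feature classes for one (already filtered) image."""
    box = _bbox(mask)
    img_c, mask_c = image[box], mask[box]
    disc = discretize(img_c, mask_c, scheme=scheme, bin_width=bin_width, bin_count=bin_count)
    out = {}
    voxel_volume = float(np.prod(spacing))
    for cls in classes:
        if cls == "firstorder":
            feats = first_order_features(img_c, mask_c, disc, voxel_volume=voxel_volume)
        else:
            feats = texture_features(build_texture_matrix(disc, cls.upper()))
        for name, value in feats.items():
            out[f"{cls}__{name}"] = value
    return out


def extract_feature_vector(
    maps: dict,
    region_mask: np.ndarray,
    region_label: str,
    spacing=(1.0, 1.0, 1.0),
    filters: list[FilterSpec] | None = None,
    classes=FEATURE_CLASSES,
    bin_width: float = 25.0,
    scheme: str = "fixed_bin_width",
    bin_count: int = 32,
    min_voxels: int = 10,
) -> dict:
    """Full map x filter x class x feature cross product for one subject.

    ``maps`` maps perfusion-map names to volumes; the same region mask is
    applied to each.  Raises :class:`RegionTooSmallError` when the region
    has fewer than ``min_voxels`` voxels.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    n = int(region_mask.sum())
    if n < min_voxels:
        raise RegionTooSmallError(
            f"region {region_label!r} has {n} voxels (< {min_voxels}); subject flagged"
        )
    filters = default_filter_bank() if filters is None else filters
    vector = {}
    for map_name, volume in maps.items():
        volume = np.asarray(volume, dtype=float)
        if volume.shape != region_mask.shape:
            raise ValueError(f"map {map_name!r} shape mismatch with region mask")
        for spec in filters:
            filtered = apply_filter(volume, spec, spacing)
            feats = extract_features_single(
                filtered, region_mask, spacing=spacing, classes=classes,
                bin_width=bin_width, scheme=scheme, bin_count=bin_count,
            )
            for key, value in feats.items():
                vector[f"{region_label}__{map_name}__{spec.label}__{key}"] = value
    return vector


def cohort_feature_table(
    subjects,
    masks: dict,
    region_label: str,
    filters: list[FilterSpec] | None = None,
    classes=FEATURE_CLASSES,
    bin_width: float = 25.0,
    min_voxels: int = 10,
) -> tuple[pd.DataFrame, list]:
    """Extract one region's features for every subject.

    ``masks`` maps subject_id to the region's binary mask.  Returns the
    feature table (rows indexed by subject_id) plus the list of flagged
    subject_ids whose region was too small; flagged subjects are omitted,
    never filled with fabricated values.
    """
    rows, flagged = {}, []
    for subj in subjects:
        try:
            rows[subj.subject_id] = extract_feature_vector(
                subj.maps, masks[subj.subject_id], region_label,
                spacing=subj.voxel_spacing, filters=filters, classes=classes,
                bin_width=bin_width, min_voxels=min_voxels,
            )
        except RegionTooSmallError:
            flagged.append(subj.subject_id)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table, flagged
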