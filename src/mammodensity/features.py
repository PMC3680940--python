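"""Fixed-layout per-image feature vectors.

Every image yields one fixed-length named vector assembled from: whole-breast
intensity statistics; for each thresholding method, a pass on the preprocessed
image (variant ``A``: whole-region statistics plus a single 5+-pixel object
size class) and a pass on the background-subtracted, de-noised, watershed-split
image (variant ``B``: three object size classes); a Sobel edge pass; and a
thinning (centerline) pass.  Statistics that cannot be computed (empty dense
mask, failed method) are NaN — a pass failure never aborts the vector.

The slot order is owned by a versioned :class:`FeatureLayout` registry whose
hash is stable across runs and platforms; correctness downstream is defined
against the registry, not any particular slot count.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import BreastMask, GrayImage
from .segment import (SIZE_CLASS_5PLUS, SIZE_CLASSES_WATERSHED,
                      SIZECLASS_STATS, denoise, find_edges, measure_objects,
                      region_stats, rolling_ball_subtract, summarize_sizeclass,
                      thin, watershed_split)
from .thresholds import (THRESHOLD_METHODS, Histogram, apply_threshold,
                         auto_threshold, build_histogram)

__all__ = ["FeatureLayout", "default_layout", "extract_features",
           "write_feature_table", "read_feature_table"]

WHOLE_STATS = ["area_fraction", "dense_area", "mean", "median", "mode",
               "intden", "skew", "kurt"]
BREAST_STATS = ["area", "mean", "median", "mode", "intden", "skew", "kurt"]
EDGE_STATS = ["mean", "median", "mode", "intden", "skew", "kurt"]
THIN_STATS = ["count", "total_length", "mean_gray", "intden"]


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered slot registry for feature vectors."""

    slots: tuple
    roster: tuple
    version: str = "1"

    @property
    def layout_hash(self) -> str:
        payload = (self.version + "\n" + "\n".join(self.slots)).encode()
        return hashlib.sha256(payload).hexdigest()

    def __len__(self) -> int:
        return len(self.slots)


def default_layout(roster=None, version: str = "1") -> FeatureLayout:
    """Build the default layout for a threshold-method roster (all 15 by
    default)."""
    roster = tuple(roster or THRESHOLD_METHODS)
    slots: list[str] = []
    slots += [f"breast|{s}" for s in BREAST_STATS]
    for m in roster:
        slots += [f"A|{m}|whole|{s}" for s in WHOLE_STATS]
        for name, _, _ in SIZE_CLASS_5PLUS:
            slots += [f"A|{m}|{name}|{s}" for s in SIZECLASS_STATS]
    for m in roster:
        for name, _, _ in SIZE_CLASSES_WATERSHED:
            slots += [f"B|{m}|{name}|{s}" for s in SIZECLASS_STATS]
    slots += [f"edge|whole|{s}" for s in EDGE_STATS]
    slots += [f"thin|{s}" for s in THIN_STATS]
    return FeatureLayout(slots=tuple(slots), roster=roster, version=version)


_EIGHT = np.ones((3, 3), dtype=int)


def _method_pass(image: GrayImage, mask_arr: np.ndarray, breast_area: int,
                 hist: Histogram, method: str, variant: str,
                 out: dict, watershed_variant: bool) -> None:
    prefix = f"{variant}|{method}"
    try:
        level = auto_threshold(hist, method)
    except Exception:
        return  # all slots for this pass stay NaN
    dense, frac = apply_threshold(image, BreastMask(mask=mask_arr), level)
    if variant == "A":
        vals = image.pixels[dense]
        out[f"{prefix}|whole|area_fraction"] = 100.0 * frac
        out[f"{prefix}|whole|dense_area"] = float(dense.sum())
        for k, v in region_stats(vals).items():
            out[f"{prefix}|whole|{k}"] = v
    if watershed_variant:
        labels = watershed_split(dense)
        classes = SIZE_CLASSES_WATERSHED
    else:
        labels, n_lab = ndi.label(dense, structure=_EIGHT)
        classes = SIZE_CLASS_5PLUS
        if n_lab:
            # only the 5+ px class is summarized; drop speckles up front
            areas = np.bincount(labels.ravel())
            small = np.flatnonzero(areas[1:] < 5) + 1
            if small.size:
                labels[np.isin(labels, small)] = 0
    objects = measure_objects(labels, image)
    summary = summarize_sizeclass(objects, classes, reference_area=breast_area)
    for _, row in summary.iterrows():
        for stat in SIZECLASS_STATS:
            out[f"{prefix}|{row['size_class']}|{stat}"] = row[stat]


def extract_features(image: GrayImage, mask: BreastMask,
                     layout: FeatureLayout | None = None,
                     rolling_ball_radius: int = 50,
                     denoise_method: str = "median", denoise_size: int = 3,
                     thin_method: str = "Moments") -> pd.Series:
    """Compute the full fixed-layout feature vector for one image.

    Deterministic: the same image and mask always produce a bit-identical
    vector.  ``thin_method`` selects which variant-A dense mask feeds the
    centerline (thinning) pass.
    """
    layout = layout or default_layout()
    mask_arr = mask.mask
    breast_area = mask.breast_area
    if breast_area == 0:
        raise ValueError("empty breast mask")
    out: dict[str, float] = {}

    breast_vals = image.pixels[mask_arr]
    out["breast|area"] = float(breast_area)
    for k, v in region_stats(breast_vals).items():
        out[f"breast|{k}"] = v

    hist_a = build_histogram(image, mask)
    for m in layout.roster:
        _method_pass(image, mask_arr, breast_area, hist_a, m, "A", out,
                     watershed_variant=False)

    try:
        image_b = denoise(rolling_ball_subtract(image, rolling_ball_radius),
                          method=denoise_method, size=denoise_size)
        hist_b = build_histogram(image_b, mask)
    except Exception:
        image_b = hist_b = None
    if hist_b is not None:
        for m in layout.roster:
            _method_pass(image_b, mask_arr, breast_area, hist_b, m, "B", out,
                         watershed_variant=True)

    edges = find_edges(image)
    for k, v in region_stats(edges.pixels[mask_arr]).items():
        out[f"edge|whole|{k}"] = v

    try:
        level = auto_threshold(hist_a, thin_method)
        dense, _ = apply_threshold(image, mask, level)
        skeleton = thin(dense)
        n_comp = int(ndi.label(skeleton, structure=_EIGHT)[1])
        skel_vals = image.pixels[skeleton]
        out["thin|count"] = float(n_comp)
        out["thin|total_length"] = float(skeleton.sum())
        out["thin|mean_gray"] = float(skel_vals.mean()) if skel_vals.size else np.nan
        out["thin|intden"] = float(skel_vals.sum(dtype=np.float64)) if skel_vals.size else np.nan
    except Exception:
        pass

    return pd.Series([out.get(s, np.nan) for s in layout.slots],
                     index=list(layout.slots), dtype=float)


def write_feature_table(rows: dict[str, pd.Series], path,
                        layout: FeatureLayout | None = None) -> pd.DataFrame:
    """Persist feature vectors as CSV: first column image id, then slot
    columns; NaN serialized as the string ``NaN``."""
    layout = layout or default_layout()
    table = pd.DataFrame({k: v for k, v in rows.items()}).T
    table = table[list(layout.slots)]
    table.index.name = "id"
    table.to_csv(path, na_rep="NaN")
    return table


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
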