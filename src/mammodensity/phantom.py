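"""Seeded mammogram-like phantom images and case-control cohorts.

A phantom is a bright half-elliptical "breast" attached to the left edge of a
dark film background, with dense fibroglandular tissue emulated as a smoothed
Gaussian-blob field thresholded at the quantile that achieves a requested
ground-truth percent density (PD).  Optional corner identification tag,
multiplicative vignetting and additive Gaussian noise emulate film-digitization
artifacts.  Ground truth (breast mask, dense mask, true PD) is captured before
noise, so it is exact.

Cohorts draw per-subject PD on the square-root scale (where PD is close to
normal), with cases shifted upward by a configurable amount.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import GrayImage, save_image

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters fully determining one phantom image (given the seed)."""

    height: int = 256
    width: int = 256
    target_pd: float = 25.0           # percent, 0..100
    n_blobs: int = 12                 # dense-tissue Gaussian blobs
    blob_sigma: float = 9.0           # px, blob scale
    tag: bool = False                 # corner identification-tag artifact
    noise_sd: float = 0.015           # additive Gaussian noise, fraction of range
    vignetting: float = 0.15          # multiplicative radial falloff strength
    bit_depth: int = 12
    background_level: float = 0.04    # film background, fraction of range
    tissue_level: float = 0.38        # non-dense breast tissue, fraction of range
    dense_level: float = 0.30         # added on top of tissue for dense pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_pd <= 100.0):
            raise ValueError("target_pd must be in [0, 100]")
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom smaller than 32x32 is not supported")


@dataclass(frozen=True)
class PhantomTruth:
    """Exact pre-noise ground truth for a phantom."""

    breast_mask: np.ndarray
    dense_mask: np.ndarray
    tag_mask: np.ndarray

    @property
    def breast_area(self) -> int:
        return int(self.breast_mask.sum())

    @property
    def dense_area(self) -> int:
        return int(self.dense_mask.sum())

    @property
    def pd(self) -> float:
        return 100.0 * self.dense_area / self.breast_area


def _breast_region(spec: PhantomSpec) -> np.ndarray:
    """Half-ellipse attached to the left edge (chest wall), MLO-like."""
    h, w = spec.height, spec.width
    cy = 0.52 * h
    a = 0.78 * w          # horizontal semi-axis, from the left edge
    b = 0.42 * h          # vertical semi-axis
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return ((xx / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0


def _dense_field(spec: PhantomSpec, breast: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Smooth random field over the breast; higher values = denser tissue."""
    h, w = spec.height, spec.width
    field_img = np.zeros((h, w), dtype=np.float64)
    rows, cols = np.nonzero(breast)
    # blob centres biased toward the central breast (fibroglandular core)
    centre_bias = 0.35
    cy, cx = rows.mean(), cols.mean()
    for _ in range(spec.n_blobs):
        i = rng.integers(0, rows.size)
        r = (1 - centre_bias) * rows[i] + centre_bias * cy
        c = (1 - centre_bias) * cols[i] + centre_bias * cx
        amp = rng.uniform(0.5, 1.0)
        sig = spec.blob_sigma * rng.uniform(0.6, 1.4)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        field_img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sig ** 2))
    # smooth texture component so the quantile cut is not blob-circular
    texture = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    field_img += 0.35 * texture / max(texture.std(), 1e-12)
    return field_img


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, PhantomTruth]:
    """Render one phantom and its exact ground truth.

    The dense mask is the top-k pixels of the smooth dense field inside the
    breast, with k chosen so true PD matches ``spec.target_pd`` to within half
    a pixel's worth of area.  Same seed, same spec -> bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    breast = _breast_region(spec)
    breast_area = int(breast.sum())

    k = int(round(spec.target_pd / 100.0 * breast_area))
    if k > breast_area:
        raise ValueError("unattainable target PD")
    dense = np.zeros((h, w), dtype=bool)
    if k > 0:
        field_img = _dense_field(spec, breast, rng)
        vals = field_img[breast]
        order = np.argsort(vals)[::-1][:k]
        rows, cols = np.nonzero(breast)
        dense[rows[order], cols[order]] = True
    else:
        # keep the RNG stream aligned regardless of target PD
        _ = _dense_field(spec, breast, rng)

    tag = np.zeros((h, w), dtype=bool)
    if spec.tag:
        th, tw = max(8, h // 12), max(16, w // 6)
        tag[2: 2 + th, w - 2 - tw: w - 2] = True

    full = float((1 << spec.bit_depth) - 1)
    img = np.full((h, w), spec.background_level, dtype=np.float64)
    img[breast] = spec.tissue_level
    img[dense] += spec.dense_level
    # smooth tissue boundary slightly (film blur)
    img = ndi.gaussian_filter(img, sigma=1.0)
    if spec.vignetting > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        img *= 1.0 - spec.vignetting * r2 / 2.0
    img[tag] = 0.92
    img += spec.noise_sd * rng.standard_normal((h, w))
    pixels = np.clip(np.round(img * full), 0, full).astype(np.uint16)

    gray = GrayImage(pixels=pixels, bit_depth=spec.bit_depth)
    truth = PhantomTruth(breast_mask=breast, dense_mask=dense, tag_mask=tag)
    return gray, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _draw_sqrt_pd(rng: np.random.Generator, n: int, mean: float, sd: float,
                  shift: float = 0.0) -> np.ndarray:
    """Truncated-normal draw on the sqrt-PD scale (right-skewed PD)."""
    lo, hi = 0.0, 9.5
    out = np.empty(n)
    for i in range(n):
        while True:
            v = rng.normal(mean + shift, sd)
            if lo <= v <= hi:
                out[i] = v
                break
    return out


def generate_cohort(n_cases: int, n_controls: int, pd_shift: float = 0.8,
                    template: PhantomSpec | None = None, seed: int = 0,
                    out_dir=None, sqrt_pd_mean: float = 3.4,
                    sqrt_pd_sd: float = 1.3):
    """Seeded case-control phantom cohort with known truth.

    Per-subject target PD is drawn on the sqrt scale (truncated normal, mean
    ``sqrt_pd_mean``, sd ``sqrt_pd_sd``, reflecting the right-skewed PD
    distributions seen in screening populations); cases are shifted upward by
    ``pd_shift`` on the sqrt-PD scale.  Returns ``(images, manifest)`` where
    ``manifest`` is a DataFrame with id, status, true pd / areas and the
    per-image seed.  If ``out_dir`` is given, images (PNG), ``labels.csv``,
    ``truth.csv`` and ``manifest.json`` are written there.
    """
    if pd_shift < 0:
        raise ValueError("pd_shift must be >= 0")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    statuses = [1] * n_cases + [0] * n_controls
    sqrt_pds = np.concatenate([
        _draw_sqrt_pd(rng, n_cases, sqrt_pd_mean, sqrt_pd_sd, shift=pd_shift),
        _draw_sqrt_pd(rng, n_controls, sqrt_pd_mean, sqrt_pd_sd, shift=0.0),
    ])
    images = []
    records = []
    for i, (status, s) in enumerate(zip(statuses, sqrt_pds)):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = PhantomSpec(
            height=template.height, width=template.width,
            target_pd=float(min(s ** 2, 100.0)),
            n_blobs=template.n_blobs, blob_sigma=template.blob_sigma,
            tag=template.tag, noise_sd=template.noise_sd,
            vignetting=template.vignetting, bit_depth=template.bit_depth,
            background_level=template.background_level,
            tissue_level=template.tissue_level,
            dense_level=template.dense_level, seed=sub_seed,
        )
        img, truth = generate_phantom(spec)
        image_id = f"subj{i:04d}"
        images.append((image_id, img, truth))
        records.append({
            "id": image_id, "status": status, "pd": truth.pd,
            "dense_area": truth.dense_area, "breast_area": truth.breast_area,
            "seed": sub_seed,
        })
    manifest = pd.DataFrame.from_records(records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for image_id, img, _ in images:
            save_image(img, out_dir / f"{image_id}.png")
        manifest[["id", "status"]].to_csv(out_dir / "labels.csv", index=False)
        manifest[["id", "pd", "dense_area", "breast_area"]].to_csv(
            out_dir / "truth.csv", index=False)
        meta = {"template": asdict(template), "seed": seed,
                "n_cases": n_cases, "n_controls": n_controls,
                "pd_shift": pd_shift,
                "manifest_sha256": hashlib.sha256(
                    manifest.to_csv(index=False).encode()).hexdigest()}
        (out_dir / "manifest.json").write_text(json.dumps(meta, indent=2))
    return images, manifest
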