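"""Global histogram-based automatic thresholding.

Implements the fifteen classical auto-threshold algorithms used for dense-tissue
segmentation (IsoData, Huang, Intermodes, Li, MaxEntropy, Mean, MinError, Minimum,
Moments, Otsu, Percentile, RenyiEntropy, Shanbhag, Triangle, Yen), operating on
256-level grayscale histograms.  A returned threshold ``t`` splits levels into
background ``<= t`` and foreground ``> t``; ties between equally good split
points are broken toward the lower level.

All methods are deterministic and invariant to multiplying every histogram
count by a positive constant (they work on the normalised distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Histogram",
    "THRESHOLD_METHODS",
    "MethodFailure",
    "DegenerateHistogramError",
    "build_histogram",
    "auto_threshold",
    "min_error_threshold",
    "apply_threshold",
    "threshold_all",
]

_EPS = 1e-12


class DegenerateHistogramError(ValueError):
    """Histogram carries mass on fewer than two distinct levels."""


class MethodFailure(RuntimeError):
    """A thresholding method failed to converge / produce a valid level."""


@dataclass(frozen=True)
class Histogram:
    """Per-level pixel counts over a masked image region."""

    counts: np.ndarray
    n_levels: int = 256

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 1 or counts.size != self.n_levels:
            raise ValueError(
                f"counts must be 1-D of length n_levels={self.n_levels}, got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram must have positive total mass")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def n_nonzero_levels(self) -> int:
        return int(np.count_nonzero(self.counts))

    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_csv(self, path) -> None:
        levels = np.arange(self.n_levels)
        np.savetxt(path, np.column_stack([levels, self.counts]),
                   fmt=("%d", "%.10g"), delimiter=",", header="level,count", comments="")

    @classmethod
    def from_csv(cls, path) -> "Histogram":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        counts = np.asarray(data)[:, 1]
        return cls(counts=counts, n_levels=len(counts))


# ---------------------------------------------------------------------------
# histogram construction / application
# ---------------------------------------------------------------------------

def _bin_of(values: np.ndarray, bit_depth: int, n_levels: int) -> np.ndarray:
    """Map raw intensities to histogram bins by linear rescale of the full range."""
    full = 1 << bit_depth
    if full == n_levels:
        return values.astype(np.int64)
    binned = (values.astype(np.int64) * n_levels) // full
    return np.clip(binned, 0, n_levels - 1)


def build_histogram(image, mask=None, n_levels: int = 256) -> Histogram:
    """Histogram of intensities inside ``mask`` (a BreastMask or boolean raster).

    Deeper-than-8-bit images are linearly rescaled into ``n_levels`` bins so the
    classic 256-bin threshold formulations apply regardless of bit depth.
    """
    pixels = image.pixels
    bit_depth = image.bit_depth
    if mask is None:
        values = pixels.ravel()
    else:
        m = mask.mask if hasattr(mask, "mask") else np.asarray(mask, dtype=bool)
        if not m.any():
            raise ValueError("empty mask: histogram undefined")
        values = pixels[m]
    bins = _bin_of(values, bit_depth, n_levels)
    counts = np.bincount(bins, minlength=n_levels).astype(np.float64)
    return Histogram(counts=counts, n_levels=n_levels)


def apply_threshold(image, mask, level: int, n_levels: int = 256):
    """Binary dense-tissue mask: pixels inside the breast whose (rescaled) level
    is strictly above ``level``.  Returns ``(dense_mask, area_fraction)``."""
    m = mask.mask if hasattr(mask, "mask") else np.asarray(mask, dtype=bool)
    bins = _bin_of(image.pixels, image.bit_depth, n_levels)
    dense = (bins > level) & m
    area = int(m.sum())
    frac = float(dense.sum()) / area if area else 0.0
    return dense, frac


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _validate(hist: Histogram) -> np.ndarray:
    if hist.n_nonzero_levels < 2:
        raise DegenerateHistogramError("histogram has mass on fewer than two levels")
    return hist.probabilities()


def _nonzero_span(p: np.ndarray) -> tuple[int, int]:
    nz = np.flatnonzero(p > 0)
    return int(nz[0]), int(nz[-1])


# ---------------------------------------------------------------------------
# the 15 methods
# ---------------------------------------------------------------------------

def _isodata(p: np.ndarray) -> int:
    """Ridler–Calvard iterative intermeans: ascend g until g equals the rounded
    midpoint of the means below g and above g (bin g excluded from both)."""
    L = p.size
    levels = np.arange(L, dtype=np.float64)
    nz = np.flatnonzero(p > 0)
    g = int(nz[0]) + 1
    while g <= L - 2:
        wl = p[:g].sum()
        wh = p[g + 1:].sum()
        if wl > 0 and wh > 0:
            ml = (levels[:g] * p[:g]).sum() / wl
            mh = (levels[g + 1:] * p[g + 1:]).sum() / wh
            if g == int(round((ml + mh) / 2.0)):
                return g
        g += 1
    raise MethodFailure("IsoData did not converge")


def _huang(p: np.ndarray) -> int:
    """Huang & Wang fuzzy-entropy minimisation (Shannon form)."""
    first, last = _nonzero_span(p)
    if first == last:
        raise DegenerateHistogramError("single-level histogram")
    levels = np.arange(p.size, dtype=np.float64)
    C = float(last - first)
    W = np.cumsum(p)
    S = np.cumsum(p * levels)
    Wt = W[-1]
    St = S[-1]
    best_t, best_e = first, np.inf
    for t in range(first, last):
        w0 = W[t]
        w1 = Wt - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = S[t] / w0
        mu1 = (St - S[t]) / w1
        # membership of each level to its assigned class
        mu = np.empty(p.size)
        mu[: t + 1] = 1.0 / (1.0 + np.abs(levels[: t + 1] - mu0) / C)
        mu[t + 1:] = 1.0 / (1.0 + np.abs(levels[t + 1:] - mu1) / C)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        s = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        e = float((p * s).sum())
        if e < best_e - _EPS:
            best_e, best_t = e, t
    return best_t


def _smooth_until_bimodal(p: np.ndarray, max_iter: int = 10000) -> np.ndarray:
    """Iterated length-3 mean filter until the histogram has exactly two local maxima."""
    h = p.astype(np.float64).copy()
    for _ in range(max_iter):
        if _count_peaks(h) == 2:
            return h
        padded = np.concatenate([h[:1], h, h[-1:]])
        h = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    raise MethodFailure("histogram could not be smoothed to bimodality")


def _count_peaks(h: np.ndarray) -> int:
    mid = h[1:-1]
    return int(np.count_nonzero((h[:-2] < mid) & (h[2:] <= mid)))


def _intermodes(p: np.ndarray) -> int:
    h = _smooth_until_bimodal(p)
    peaks = [i for i in range(1, h.size - 1) if h[i - 1] < h[i] and h[i + 1] <= h[i]]
    return int((peaks[0] + peaks[1]) // 2)


def _minimum(p: np.ndarray) -> int:
    h = _smooth_until_bimodal(p)
    for i in range(1, h.size - 1):
        if h[i - 1] > h[i] and h[i + 1] >= h[i]:
            return i
    raise MethodFailure("no valley found in bimodal histogram")


def _li(p: np.ndarray) -> int:
    """Minimum cross-entropy (Li & Tam criterion) by exhaustive scan.

    Levels are shifted by +1 inside the criterion so level 0 has a defined
    logarithm; ties go to the lower level.
    """
    first, last = _nonzero_span(p)
    g = np.arange(p.size, dtype=np.float64) + 1.0
    W = np.cumsum(p)
    A = np.cumsum(p * g)
    Wt, At = W[-1], A[-1]
    best_t, best_c = first, np.inf
    for t in range(first, last):
        w0, w1 = W[t], Wt - W[t]
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = A[t] / w0
        mu1 = (At - A[t]) / w1
        crit = -(A[t] * np.log(mu0) + (At - A[t]) * np.log(mu1))
        if crit < best_c - _EPS:
            best_c, best_t = crit, t
    return best_t


def _max_entropy(p: np.ndarray) -> int:
    """Kapur–Sahoo–Wong maximum Shannon entropy of the two classes."""
    first, last = _nonzero_span(p)
    P1 = np.cumsum(p)
    best_t, best_h = first, -np.inf
    for t in range(first, last):
        w0, w1 = P1[t], 1.0 - P1[t]
        if w0 <= _EPS or w1 <= _EPS:
            continue
        p0 = p[: t + 1] / w0
        p1 = p[t + 1:] / w1
        h0 = -np.sum(p0[p0 > 0] * np.log(p0[p0 > 0]))
        h1 = -np.sum(p1[p1 > 0] * np.log(p1[p1 > 0]))
        if h0 + h1 > best_h + _EPS:
            best_h, best_t = h0 + h1, t
    return best_t


def _mean(p: np.ndarray) -> int:
    levels = np.arange(p.size, dtype=np.float64)
    return int(np.floor((levels * p).sum()))


def _min_error(p: np.ndarray) -> int:
    """Kittler–Illingworth minimum-error criterion, exhaustive scan.

    J(t) = 1 + 2 [P0 ln s0 + P1 ln s1] - 2 [P0 ln P0 + P1 ln P1]; class standard
    deviations are floored at the quantisation value sqrt(1/12) so delta-spike
    classes keep the criterion defined.
    """
    first, last = _nonzero_span(p)
    levels = np.arange(p.size, dtype=np.float64)
    W = np.cumsum(p)
    M = np.cumsum(p * levels)
    Q = np.cumsum(p * levels ** 2)
    var_floor = 1.0 / 12.0
    best_t, best_j = None, np.inf
    for t in range(first, last):
        w0, w1 = W[t], W[-1] - W[t]
        if w0 <= _EPS or w1 <= _EPS:
            continue
        mu0 = M[t] / w0
        mu1 = (M[-1] - M[t]) / w1
        v0 = max(Q[t] / w0 - mu0 ** 2, var_floor)
        v1 = max((Q[-1] - Q[t]) / w1 - mu1 ** 2, var_floor)
        j = 1.0 + w0 * np.log(v0) + w1 * np.log(v1) - 2.0 * (
            w0 * np.log(w0) + w1 * np.log(w1))
        if j < best_j - _EPS:
            best_j, best_t = j, t
    if best_t is None:
        raise MethodFailure("minimum-error criterion undefined for this histogram")
    return best_t


def _moments(p: np.ndarray) -> int:
    """Tsai moment-preserving threshold: find the fraction p0 that preserves the
    first three moments under a bilevel image, then take the p0-fractile."""
    levels = np.arange(p.size, dtype=np.float64)
    m1 = float((levels * p).sum())
    m2 = float((levels ** 2 * p).sum())
    m3 = float((levels ** 3 * p).sum())
    cd = m2 - m1 * m1
    if abs(cd) < _EPS:
        raise DegenerateHistogramError("zero-variance histogram")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 / 4.0 - c0, 0.0)
    z0 = -c1 / 2.0 - np.sqrt(disc)
    z1 = -c1 / 2.0 + np.sqrt(disc)
    if abs(z1 - z0) < _EPS:
        raise MethodFailure("moment-preserving roots coincide")
    p0 = (z1 - m1) / (z1 - z0)
    # p0-fractile: smallest level whose cumulative mass reaches p0
    csum = 0.0
    for t in range(p.size):
        csum += p[t]
        if csum >= p0 - 1e-12:
            return t
    return p.size - 1


def _otsu(p: np.ndarray) -> int:
    """Maximise between-class variance; ties toward the lower level."""
    first, last = _nonzero_span(p)
    levels = np.arange(p.size, dtype=np.float64)
    W = np.cumsum(p)
    M = np.cumsum(p * levels)
    mu_t = M[-1]
    best_t, best_v = first, -np.inf
    for t in range(first, last):
        w0, w1 = W[t], 1.0 - W[t]
        if w0 <= _EPS or w1 <= _EPS:
            continue
        mu0 = M[t] / w0
        mu1 = (mu_t - M[t]) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + _EPS:
            best_v, best_t = v, t
    return best_t


def _percentile(p: np.ndarray, ptile: float = 0.5) -> int:
    """Doyle's percentile method: split so the background mass is closest to
    ``ptile`` (default half); near-ties (within 1e-12) toward the lower level."""
    P1 = np.cumsum(p)
    first, last = _nonzero_span(p)
    best_t, best_d = first, np.inf
    for t in range(first, last):
        d = abs(P1[t] - ptile)
        if d < best_d - 1e-12:
            best_d, best_t = d, t
    return best_t


def _renyi_entropy_t(p: np.ndarray, alpha: float) -> int:
    """Threshold maximising the two-class Renyi entropy of order ``alpha``."""
    first, last = _nonzero_span(p)
    P1 = np.cumsum(p)
    best_t, best_h = first, -np.inf
    for t in range(first, last):
        w0, w1 = P1[t], 1.0 - P1[t]
        if w0 <= _EPS or w1 <= _EPS:
            continue
        q0 = p[: t + 1] / w0
        q1 = p[t + 1:] / w1
        if alpha == 1.0:
            h0 = -np.sum(q0[q0 > 0] * np.log(q0[q0 > 0]))
            h1 = -np.sum(q1[q1 > 0] * np.log(q1[q1 > 0]))
            h = h0 + h1
        else:
            s0 = np.sum(q0 ** alpha)
            s1 = np.sum(q1 ** alpha)
            if s0 <= 0 or s1 <= 0:
                continue
            h = (np.log(s0) + np.log(s1)) / (1.0 - alpha)
        if h > best_h + _EPS:
            best_h, best_t = h, t
    return best_t


def _renyi_entropy(p: np.ndarray) -> int:
    """Sahoo's three-order Renyi combination (orders 1/2, 1 and 2) with the
    proximity-weighted fusion rule."""
    P1 = np.cumsum(p)
    ts = sorted([_renyi_entropy_t(p, 0.5), _renyi_entropy_t(p, 1.0),
                 _renyi_entropy_t(p, 2.0)])
    t1, t2, t3 = ts
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 1, 2, 1
        else:
            b1, b2, b3 = 0, 1, 3
    else:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 3, 1, 0
        else:
            b1, b2, b3 = 1, 2, 1
    omega = P1[t3] - P1[t1]
    t_opt = (t1 * (P1[t1] + 0.25 * omega * b1)
             + 0.25 * t2 * omega * b2
             + t3 * (1.0 - P1[t3] + 0.25 * omega * b3))
    return int(t_opt)


def _shanbhag(p: np.ndarray) -> int:
    """Shanbhag's fuzzy-information measure: minimise |information(background)
    - information(foreground)|."""
    first, last = _nonzero_span(p)
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    best_t, best_d = first, np.inf
    for t in range(first, last):
        w0, w1 = P1[t], P2[t]
        if w0 <= _EPS or w1 <= _EPS:
            continue
        term0 = 0.5 / w0
        if t >= 1:
            arg = 1.0 - term0 * P1[:t]          # P1[i-1] for i = 1..t
            valid = (arg > 0) & (p[1: t + 1] > 0)
            ent_back = -term0 * float(np.sum(p[1: t + 1][valid] * np.log(arg[valid])))
        else:
            ent_back = 0.0
        term1 = 0.5 / w1
        if t + 1 <= p.size - 2:
            arg = 1.0 - term1 * P2[t + 2:]      # P2[i+1] for i = t+1..L-2
            valid = (arg > 0) & (p[t + 1: p.size - 1] > 0)
            ent_obj = -term1 * float(
                np.sum(p[t + 1: p.size - 1][valid] * np.log(arg[valid])))
        else:
            ent_obj = 0.0
        d = abs(ent_back - ent_obj)
        if d < best_d - _EPS:
            best_d, best_t = d, t
    return best_t


def _triangle(p: np.ndarray) -> int:
    """Zack's triangle method: maximal perpendicular distance from the histogram
    to the line joining its peak and the far end of its support; the histogram
    is flipped when its long tail lies to the left."""
    h = p.astype(np.float64).copy()
    nz = np.flatnonzero(h > 0)
    xmin = max(int(nz[0]) - 1, 0)
    xmax = min(int(nz[-1]) + 1, h.size - 1)
    peak = int(np.argmax(h))
    inverted = (peak - xmin) < (xmax - peak)
    # ensure the long tail is to the LEFT of the peak (as in the classic
    # formulation), flipping when necessary
    if inverted:
        h = h[::-1]
        xmin, xmax = h.size - 1 - xmax, h.size - 1 - xmin
        peak = h.size - 1 - peak
    if peak == xmin:
        t = peak
    else:
        hm = h[peak]
        nx = hm          # line normal components (unnormalised)
        ny = float(peak - xmin)
        d_best, t = -np.inf, xmin
        for i in range(xmin + 1, peak + 1):
            d = nx * (i - xmin) - ny * h[i]
            if d > d_best:
                d_best, t = d, i
        t -= 1
    if inverted:
        t = h.size - 1 - t
    return int(t)


def _yen(p: np.ndarray) -> int:
    """Yen's maximum-correlation criterion."""
    first, last = _nonzero_span(p)
    P1 = np.cumsum(p)
    P1sq = np.cumsum(p ** 2)
    Ptot_sq = P1sq[-1]
    best_t, best_c = first, -np.inf
    for t in range(first, last):
        w0, w1 = P1[t], 1.0 - P1[t]
        s0, s1 = P1sq[t], Ptot_sq - P1sq[t]
        if s0 <= 0 or s1 <= 0 or w0 <= _EPS or w1 <= _EPS:
            continue
        c = -np.log(s0 * s1 / (w0 * w0 * w1 * w1))
        if c > best_c + _EPS:
            best_c, best_t = c, t
    return best_t


THRESHOLD_METHODS: dict[str, callable] = {
    "IsoData": _isodata,
    "Huang": _huang,
    "Intermodes": _intermodes,
    "Li": _li,
    "MaxEntropy": _max_entropy,
    "Mean": _mean,
    "MinError": _min_error,
    "Minimum": _minimum,
    "Moments": _moments,
    "Otsu": _otsu,
    "Percentile": _percentile,
    "RenyiEntropy": _renyi_entropy,
    "Shanbhag": _shanbhag,
    "Triangle": _triangle,
    "Yen": _yen,
}


def auto_threshold(hist: Histogram, method: str) -> int:
    """Compute the threshold level for ``hist`` under the named method."""
    if method not in THRESHOLD_METHODS:
        raise KeyError(f"unknown threshold method {method!r}; "
                       f"known: {sorted(THRESHOLD_METHODS)}")
    p = _validate(hist)
    return int(THRESHOLD_METHODS[method](p))


def min_error_threshold(hist: Histogram) -> int:
    """Kittler–Illingworth minimum-error threshold (used in breast masking)."""
    p = _validate(hist)
    return int(_min_error(p))


def threshold_all(hist: Histogram, methods=None) -> dict[str, int | None]:
    """All (or the given) methods applied to one histogram; failed methods map
    to None instead of raising."""
    out: dict[str, int | None] = {}
    for name in (methods or THRESHOLD_METHODS):
        try:
            out[name] = auto_threshold(hist, name)
        except (MethodFailure, DegenerateHistogramError):
            out[name] = None
    return out
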