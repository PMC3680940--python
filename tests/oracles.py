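"""Independent oracle implementations used only by the tests.

Each function recomputes a quantity from its published definition with plain
loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# threshold objectives, exhaustive/naive forms
# ---------------------------------------------------------------------------

def _norm(counts):
    total = float(sum(counts))
    return [c / total for c in counts]


def _norm_np(counts):
    arr = np.asarray(counts, dtype=float)
    return arr / arr.sum()


def _span(p):
    nz = [i for i, v in enumerate(p) if v > 0]
    return nz[0], nz[-1]


def _prefix_sums(p):
    """Running sums of p, i*p and i^2*p (index-inclusive), built by a plain
    loop."""
    w = [0.0] * len(p)
    m = [0.0] * len(p)
    q = [0.0] * len(p)
    acc_w = acc_m = acc_q = 0.0
    for i, pi in enumerate(p):
        acc_w += pi
        acc_m += i * pi
        acc_q += i * i * pi
        w[i], m[i], q[i] = acc_w, acc_m, acc_q
    return w, m, q


def oracle_mean(counts):
    p = _norm(counts)
    mu = sum(i * pi for i, pi in enumerate(p))
    return int(math.floor(mu))


def oracle_otsu(counts):
    p = _norm(counts)
    first, last = _span(p)
    W, M, _ = _prefix_sums(p)
    best_t, best_v = first, -1.0
    for t in range(first, last):
        w0, w1 = W[t], 1.0 - W[t]
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = M[t] / w0
        mu1 = (M[-1] - M[t]) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def oracle_isodata(counts):
    L = len(counts)
    first = next(i for i, c in enumerate(counts) if c > 0)
    W, M, _ = _prefix_sums(list(counts))
    g = first + 1
    while g <= L - 2:
        wl = W[g - 1]
        wh = W[-1] - W[g]
        if wl > 0 and wh > 0:
            ml = M[g - 1] / wl
            mh = (M[-1] - M[g]) / wh
            if g == int(round((ml + mh) / 2.0)):
                return g
        g += 1
    return None


def oracle_huang(counts):
    p = _norm_np(counts)
    levels = np.arange(p.size, dtype=float)
    first, last = _span(p.tolist())
    if first == last:
        return None
    C = float(last - first)
    best_t, best_e = first, float("inf")
    for t in range(first, last):
        w0 = float(p[: t + 1].sum())
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = float((levels[: t + 1] * p[: t + 1]).sum()) / w0
        mu1 = float((levels[t + 1:] * p[t + 1:]).sum()) / w1
        centre = np.where(levels <= t, mu0, mu1)
        mu = 1.0 / (1.0 + np.abs(levels - centre) / C)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        shannon = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        e = float((p * shannon).sum())
        if e < best_e - 1e-12:
            best_e, best_t = e, t
    return best_t


_SMOOTH_CACHE: dict = {}


def _oracle_smooth_to_two_peaks(counts, max_iter=10000):
    key = tuple(counts)
    if key in _SMOOTH_CACHE:
        return _SMOOTH_CACHE[key]
    h = np.asarray(counts, dtype=float).copy()
    result = (None, None)
    for _ in range(max_iter):
        mid = h[1:-1]
        pk = (np.flatnonzero((h[:-2] < mid) & (h[2:] <= mid)) + 1).tolist()
        if len(pk) == 2:
            result = (h.tolist(), pk)
            break
        padded = np.concatenate([h[:1], h, h[-1:]])
        h = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    _SMOOTH_CACHE[key] = result
    return result


def oracle_intermodes(counts):
    h, pk = _oracle_smooth_to_two_peaks(counts)
    if h is None:
        return None
    return (pk[0] + pk[1]) // 2


def oracle_minimum(counts):
    h, pk = _oracle_smooth_to_two_peaks(counts)
    if h is None:
        return None
    for i in range(1, len(h) - 1):
        if h[i - 1] > h[i] and h[i + 1] >= h[i]:
            return i
    return None


def oracle_li(counts):
    p = _norm(counts)
    first, last = _span(p)
    W, M, _ = _prefix_sums(p)
    best_t, best_c = first, float("inf")
    for t in range(first, last):
        w0, w1 = W[t], 1.0 - W[t]
        if w0 <= 0 or w1 <= 0:
            continue
        a0 = M[t] + W[t]                      # sum (i+1) p_i, i <= t
        a1 = (M[-1] - M[t]) + (W[-1] - W[t])
        crit = -(a0 * math.log(a0 / w0) + a1 * math.log(a1 / w1))
        if crit < best_c - 1e-12:
            best_c, best_t = crit, t
    return best_t


def oracle_maxentropy(counts):
    p = _norm_np(counts)
    first, last = _span(p.tolist())
    best_t, best_h = first, -float("inf")
    for t in range(first, last):
        w0 = float(p[: t + 1].sum())
        w1 = 1.0 - w0
        if w0 <= 1e-12 or w1 <= 1e-12:
            continue
        q0 = p[: t + 1][p[: t + 1] > 0] / w0
        q1 = p[t + 1:][p[t + 1:] > 0] / w1
        h = -float((q0 * np.log(q0)).sum()) - float((q1 * np.log(q1)).sum())
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    return best_t


def oracle_minerror(counts):
    p = _norm(counts)
    first, last = _span(p)
    W, M, Q = _prefix_sums(p)
    best_t, best_j = None, float("inf")
    for t in range(first, last):
        w0, w1 = W[t], 1.0 - W[t]
        if w0 <= 1e-12 or w1 <= 1e-12:
            continue
        mu0 = M[t] / w0
        mu1 = (M[-1] - M[t]) / w1
        v0 = Q[t] / w0 - mu0 * mu0            # E[i^2] - mu^2
        v1 = (Q[-1] - Q[t]) / w1 - mu1 * mu1
        v0 = max(v0, 1.0 / 12.0)
        v1 = max(v1, 1.0 / 12.0)
        j = 1.0 + w0 * math.log(v0) + w1 * math.log(v1) \
            - 2.0 * (w0 * math.log(w0) + w1 * math.log(w1))
        if j < best_j - 1e-12:
            best_j, best_t = j, t
    return best_t


def oracle_moments(counts):
    p = _norm(counts)
    m1 = sum(i * pi for i, pi in enumerate(p))
    m2 = sum(i * i * pi for i, pi in enumerate(p))
    m3 = sum(i ** 3 * pi for i, pi in enumerate(p))
    cd = m2 - m1 * m1
    if abs(cd) < 1e-12:
        return None
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 / 4.0 - c0, 0.0)
    z0 = -c1 / 2.0 - math.sqrt(disc)
    z1 = -c1 / 2.0 + math.sqrt(disc)
    if abs(z1 - z0) < 1e-12:
        return None
    p0 = (z1 - m1) / (z1 - z0)
    s = 0.0
    for t, pi in enumerate(p):
        s += pi
        if s >= p0 - 1e-12:
            return t
    return len(p) - 1


def oracle_percentile(counts, ptile=0.5):
    p = _norm(counts)
    first, last = _span(p)
    best_t, best_d = first, float("inf")
    cum = 0.0
    for t in range(0, last):
        cum += p[t]
        if t < first:
            continue
        d = abs(cum - ptile)
        if d < best_d - 1e-12:
            best_d, best_t = d, t
    return best_t


def _oracle_renyi_single(p, alpha, first, last):
    pa = np.asarray(p, dtype=float)
    best_t, best_h = first, -float("inf")
    for t in range(first, last):
        w0 = float(pa[: t + 1].sum())
        w1 = 1.0 - w0
        if w0 <= 1e-12 or w1 <= 1e-12:
            continue
        if alpha == 1.0:
            q0 = pa[: t + 1][pa[: t + 1] > 0] / w0
            q1 = pa[t + 1:][pa[t + 1:] > 0] / w1
            h = -float((q0 * np.log(q0)).sum()) - float((q1 * np.log(q1)).sum())
        else:
            s0 = float(((pa[: t + 1] / w0) ** alpha).sum())
            s1 = float(((pa[t + 1:] / w1) ** alpha).sum())
            if s0 <= 0 or s1 <= 0:
                continue
            h = (math.log(s0) + math.log(s1)) / (1.0 - alpha)
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    return best_t


def oracle_renyi(counts):
    p = _norm(counts)
    first, last = _span(p)
    stars = sorted(_oracle_renyi_single(p, a, first, last)
                   for a in (0.5, 1.0, 2.0))
    t1, t2, t3 = stars
    if abs(t1 - t2) <= 5:
        betas = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        betas = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    cum = [0.0] * len(p)
    s = 0.0
    for i, pi in enumerate(p):
        s += pi
        cum[i] = s
    omega = cum[t3] - cum[t1]
    b1, b2, b3 = betas
    t_opt = (t1 * (cum[t1] + 0.25 * omega * b1)
             + 0.25 * t2 * omega * b2
             + t3 * (1.0 - cum[t3] + 0.25 * omega * b3))
    return int(t_opt)


def oracle_shanbhag(counts):
    p = _norm(counts)
    L = len(p)
    first, last = _span(p)
    P1 = [0.0] * L
    s = 0.0
    for i, pi in enumerate(p):
        s += pi
        P1[i] = s
    P2 = [1.0 - v for v in P1]
    best_t, best_d = first, float("inf")
    for t in range(first, last):
        if P1[t] <= 1e-12 or P2[t] <= 1e-12:
            continue
        term = 0.5 / P1[t]
        pa = np.asarray(p)
        P1a = np.asarray(P1)
        P2a = np.asarray(P2)
        arg_b = 1.0 - term * P1a[0:t]          # P1[i-1], i = 1..t
        ok_b = (arg_b > 0) & (pa[1: t + 1] > 0)
        ent_back = -term * float(
            (pa[1: t + 1][ok_b] * np.log(arg_b[ok_b])).sum())
        term = 0.5 / P2[t]
        arg_o = 1.0 - term * P2a[t + 2: L]     # P2[i+1], i = t+1..L-2
        ok_o = (arg_o > 0) & (pa[t + 1: L - 1] > 0)
        ent_obj = -term * float(
            (pa[t + 1: L - 1][ok_o] * np.log(arg_o[ok_o])).sum())
        d = abs(ent_back - ent_obj)
        if d < best_d - 1e-12:
            best_d, best_t = d, t
    return best_t


def oracle_triangle(counts):
    h = [float(c) for c in counts]
    L = len(h)
    nz = [i for i, v in enumerate(h) if v > 0]
    xmin = max(nz[0] - 1, 0)
    xmax = min(nz[-1] + 1, L - 1)
    peak = max(range(L), key=lambda i: (h[i], -i))
    inverted = (peak - xmin) < (xmax - peak)
    if inverted:
        h = h[::-1]
        xmin, xmax = L - 1 - xmax, L - 1 - xmin
        peak = L - 1 - peak
    if peak == xmin:
        t = peak
    else:
        best_d, t = -float("inf"), xmin
        for i in range(xmin + 1, peak + 1):
            d = h[peak] * (i - xmin) - (peak - xmin) * h[i]
            if d > best_d:
                best_d, t = d, i
        t -= 1
    if inverted:
        t = L - 1 - t
    return t


def oracle_yen(counts):
    p = _norm(counts)
    first, last = _span(p)
    W, _, _ = _prefix_sums(p)
    Wsq, _, _ = _prefix_sums([pi * pi for pi in p])
    best_t, best_c = first, -float("inf")
    for t in range(first, last):
        w0, w1 = W[t], 1.0 - W[t]
        s0 = Wsq[t]
        s1 = Wsq[-1] - Wsq[t]
        if s0 <= 0 or s1 <= 0 or w0 <= 1e-12 or w1 <= 1e-12:
            continue
        c = -math.log(s0 * s1 / (w0 * w0 * w1 * w1))
        if c > best_c + 1e-12:
            best_c, best_t = c, t
    return best_t


THRESHOLD_ORACLES = {
    "IsoData": oracle_isodata,
    "Huang": oracle_huang,
    "Intermodes": oracle_intermodes,
    "Li": oracle_li,
    "MaxEntropy": oracle_maxentropy,
    "Mean": oracle_mean,
    "MinError": oracle_minerror,
    "Minimum": oracle_minimum,
    "Moments": oracle_moments,
    "Otsu": oracle_otsu,
    "Percentile": oracle_percentile,
    "RenyiEntropy": oracle_renyi,
    "Shanbhag": oracle_shanbhag,
    "Triangle": oracle_triangle,
    "Yen": oracle_yen,
}


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def oracle_auc_paircount(scores, labels):
    """AUC by exhaustive case-control pair comparison (ties count 1/2)."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    ctrls = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for c in cases:
        for d in ctrls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(ctrls))


def oracle_delong_variance(scores_a, scores_b, labels):
    """DeLong covariance construction by direct enumeration of placement
    values for two markers; returns the variance of the AUC difference."""
    def placements(scores):
        cases = [s for s, y in zip(scores, labels) if y == 1]
        ctrls = [s for s, y in zip(scores, labels) if y == 0]
        v_case = []
        for c in cases:
            t = 0.0
            for d in ctrls:
                t += 1.0 if d < c else (0.5 if d == c else 0.0)
            v_case.append(t / len(ctrls))
        v_ctrl = []
        for d in ctrls:
            t = 0.0
            for c in cases:
                t += 1.0 if c > d else (0.5 if c == d else 0.0)
            v_ctrl.append(t / len(cases))
        return v_case, v_ctrl

    va_case, va_ctrl = placements(scores_a)
    vb_case, vb_ctrl = placements(scores_b)
    m, n = len(va_case), len(va_ctrl)

    def cov(u, v):
        mu, mv = sum(u) / len(u), sum(v) / len(v)
        return sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)

    var = (cov(va_case, va_case) + cov(vb_case, vb_case)
           - 2 * cov(va_case, vb_case)) / m
    var += (cov(va_ctrl, va_ctrl) + cov(vb_ctrl, vb_ctrl)
            - 2 * cov(va_ctrl, vb_ctrl)) / n
    return var


def oracle_or_2x2(a, b, c, d):
    """Cross-product odds ratio of a 2x2 table (exposed cases a, unexposed
    cases b, exposed controls c, unexposed controls d)."""
    return (a / b) / (c / d)


def random_histograms(n, seed, n_levels=256):
    """Seeded bimodal-ish integer histograms for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mu0 = rng.uniform(30, 100)
        mu1 = rng.uniform(130, 230)
        s0 = rng.uniform(5, 25)
        s1 = rng.uniform(5, 30)
        n0 = int(rng.integers(200, 3000))
        n1 = int(rng.integers(200, 3000))
        x = np.concatenate([rng.normal(mu0, s0, n0), rng.normal(mu1, s1, n1)])
        x = np.clip(np.round(x), 0, n_levels - 1).astype(int)
        counts = np.bincount(x, minlength=n_levels).astype(float)
        # sprinkle background noise counts
        noise_levels = rng.integers(0, n_levels, size=30)
        for lv in noise_levels:
            counts[lv] += int(rng.integers(0, 4))
        if np.count_nonzero(counts) >= 2:
            out.append(counts)
    return out
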