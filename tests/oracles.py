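"""Independent oracle implementations used by the test suite.

Each oracle deliberately re-derives a quantity by a different route than the
package (naive loops, exhaustive search, nonlinear fitting, numerical
integration) so agreement is evidence of correctness, not of shared code.
"""

import itertools

import numpy as np
from scipy.integrate import dblquad
from scipy.optimize import least_squares


def ck_filter_naive(values, window_sizes=(2, 4, 8), weight_exponent=2.0):
    """Literal loop evaluation of the Chung-Kennedy filter formula."""
    x = [float(v) for v in values]
    n = len(x)
    eps = 1e-12

    def fwd(s, w):
        seg = x[max(0, s - w):s]
        return sum(seg) / len(seg) if seg else x[s]

    def bwd(s, w):
        seg = x[s + 1:s + 1 + w]
        return sum(seg) / len(seg) if seg else x[s]

    out = []
    for t in range(n):
        num = 0.0
        den = 0.0
        for w in window_sizes:
            ef = sum((x[s] - fwd(s, w)) ** 2 for s in range(max(0, t - w + 1), t + 1))
            eb = sum((x[s] - bwd(s, w)) ** 2 for s in range(t, min(n, t + w)))
            wf = (ef + eps) ** (-weight_exponent)
            wb = (eb + eps) ** (-weight_exponent)
            num += wf * fwd(t, w) + wb * bwd(t, w)
            den += wf + wb
        out.append(num / den)
    return np.array(out)


def gaussian_fit_centroid(roi, x0, y0):
    """Nonlinear least-squares symmetric 2-D Gaussian fit; returns (x, y)."""
    roi = np.asarray(roi, dtype=np.float64)
    h, w = roi.shape
    yy, xx = np.mgrid[:h, :w].astype(np.float64)

    def resid(params):
        amp, cx, cy, sigma, offset = params
        model = offset + amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
        )
        return (model - roi).ravel()

    amp0 = roi.max() - roi.min()
    p0 = [amp0 if amp0 > 0 else 1.0, x0, y0, 1.3, roi.min()]
    fit = least_squares(resid, p0, method="lm", max_nfev=2000)
    return float(fit.x[1]), float(fit.x[2])


def overlap_numeric(dx, dy, sigma_a, sigma_b):
    """Brute-force 2-D integration of the normalized Gaussian overlap."""

    def ga(x, y):
        return np.exp(-(x**2 + y**2) / (2 * sigma_a**2))

    def gb(x, y):
        return np.exp(-((x - dx) ** 2 + (y - dy) ** 2) / (2 * sigma_b**2))

    lim = 10 * max(sigma_a, sigma_b) + abs(dx) + abs(dy)
    cross, _ = dblquad(lambda y, x: ga(x, y) * gb(x, y), -lim, lim, -lim, lim)
    aa, _ = dblquad(lambda y, x: ga(x, y) ** 2, -lim, lim, -lim, lim)
    bb, _ = dblquad(lambda y, x: gb(x, y) ** 2, -lim, lim, -lim, lim)
    return cross / np.sqrt(aa * bb)


def otsu_objective(image, threshold, nbins=256):
    """Between-class variance achieved by splitting the histogram at threshold."""
    values = np.asarray(image, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo = counts[centers <= threshold]
    hi = counts[centers > threshold]
    clo = centers[centers <= threshold]
    chi = centers[centers > threshold]
    w0, w1 = lo.sum(), hi.sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    m0 = (lo * clo).sum() / w0
    m1 = (hi * chi).sum() / w1
    return float(w0 * w1 * (m0 - m1) ** 2)


def otsu_exhaustive(image, nbins=256):
    """Exhaustive search of the between-class-variance maximizer."""
    values = np.asarray(image, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_score, best_threshold = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        score = w0 * w1 * (m0 - m1) ** 2
        if score > best_score:
            best_score, best_threshold = score, centers[k - 1]
    return best_threshold


def brute_force_frame_matching(prev_xy, curr_xy, link_radius):
    """Exhaustive minimum-total-squared-displacement one-to-one matching.

    Enumerates all injective assignments of previous to current foci whose
    every pair lies within the link radius, maximizing the number of matches
    and among those minimizing total squared displacement.  Feasible only
    for a handful of foci.
    """
    prev_xy = np.asarray(prev_xy, dtype=np.float64)
    curr_xy = np.asarray(curr_xy, dtype=np.float64)
    np_, nc = len(prev_xy), len(curr_xy)
    best = (0, 0.0, [])
    indices = list(range(nc)) + [None] * np_
    seen = set()
    for perm in itertools.permutations(indices, np_):
        if perm in seen:
            continue
        seen.add(perm)
        used = [c for c in perm if c is not None]
        if len(used) != len(set(used)):
            continue
        pairs = []
        cost = 0.0
        ok = True
        for pi, ci in enumerate(perm):
            if ci is None:
                continue
            d2 = ((prev_xy[pi] - curr_xy[ci]) ** 2).sum()
            if d2 > link_radius**2:
                ok = False
                break
            pairs.append((pi, ci))
            cost += d2
        if not ok:
            continue
        key = (len(pairs), -cost, pairs)
        if (len(pairs), -cost) > (best[0], -best[1]):
            best = (len(pairs), cost, pairs)
    return sorted(best[2])
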