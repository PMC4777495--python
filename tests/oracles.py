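"""Independent reference implementations used only to check the package.

These deliberately avoid sharing code with :mod:`stickmotion`: the scan
oracle recomputes every distance from scratch at each step, the correlation
oracle evaluates the textbook covariance formula, and the binomial oracle
sums the probability mass function directly.
"""

import math

import numpy as np


def bruteforce_segments(points, epsilon=0.0):
    """Reference-point scan, restarted from scratch after every maximum.

    Returns (ref_frame, max_frame, max_distance, trailing) tuples.  At each
    step all distances from the current reference to the remaining frames
    are recomputed; the first frame whose successor has a strictly smaller
    distance, with the distance itself above epsilon, closes a unit.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = []
    ref = 0
    while ref < n - 1:
        dists = []
        for i in range(ref + 1, n):
            dx = points[i][0] - points[ref][0]
            dy = points[i][1] - points[ref][1]
            dists.append(math.sqrt(dx * dx + dy * dy))
        found = None
        for j in range(len(dists) - 1):
            if dists[j + 1] < dists[j] and dists[j] > epsilon:
                found = j
                break
        if found is not None:
            frame = ref + 1 + found
            out.append((ref, frame, dists[found], False))
            ref = frame
        else:
            if dists and dists[-1] > epsilon:
                out.append((ref, n - 1, dists[-1], True))
            break
    return out


def pearson_textbook(x, y):
    """Pearson r, Fisher-z 95% CI and two-sided t-test p, by the formulas."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    r = np.sum((x - mx) * (y - my)) / math.sqrt(
        np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)
    )
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    z = math.atanh(r)
    half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
    return r, math.tanh(z - half), math.tanh(z + half), p


def binom_tail(k, n, p0):
    """One-sided (greater) exact binomial p-value by direct pmf summation."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return total
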