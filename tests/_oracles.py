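"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, ray casting,
circumference sampling) and shares no code path with the estimators it
checks.
"""

import numpy as np

from sppa.geometry import isotropic_weight


def shoelace_area(vertices) -> float:
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def nnd_bruteforce(coords) -> np.ndarray:
    """Per-point nearest-neighbour distance by the O(n^2) definition."""
    coords = np.asarray(coords, float)
    n = len(coords)
    out = np.empty(n)
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(coords[i] - coords[j]))
            best = min(best, d)
        out[i] = best
    return out


def points_in_polygon(px, py, vertices):
    """Vectorised even-odd ray casting; boundary treatment irrelevant for
    the measure-zero sets sampled here."""
    v = np.asarray(vertices, float)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    px = np.asarray(px)[:, None]
    py = np.asarray(py)[:, None]
    cond = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = cond & (px < x_int)
    return crossings.sum(axis=1) % 2 == 1


def circle_inside_fraction_sampled(cx, cy, r, vertices, m=1_000_000):
    """Fraction of m equally spaced circumference points inside the ring."""
    theta = (np.arange(m) + 0.5) * (2 * np.pi / m)
    return points_in_polygon(cx + r * np.cos(theta), cy + r * np.sin(theta),
                             vertices).mean()


def _epanechnikov(t, h):
    return np.where(np.abs(t) < h, 0.75 / h * (1 - (t / h) ** 2), 0.0)


def pcf_direct(pattern, r_grid, h):
    """Direct-summation PCF: ordered-pair loop, reflected Epanechnikov
    kernel, Ripley weights from isotropic_weight, n(n-1) intensity."""
    n = pattern.n
    area = pattern.window.area
    out = np.zeros(len(r_grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(pattern.x[i] - pattern.x[j],
                         pattern.y[i] - pattern.y[j])
            w = isotropic_weight((pattern.x[i], pattern.y[i]), d,
                                 pattern.window)
            out += w * (_epanechnikov(r_grid - d, h)
                        + _epanechnikov(r_grid + d, h))
    denom = 2 * np.pi * r_grid * n * (n - 1) / area
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r_grid > 0, out / denom, np.nan)


def k_direct(pattern, r_grid):
    """Direct-summation isotropic-corrected K."""
    n = pattern.n
    area = pattern.window.area
    out = np.zeros(len(r_grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(pattern.x[i] - pattern.x[j],
                         pattern.y[i] - pattern.y[j])
            w = isotropic_weight((pattern.x[i], pattern.y[i]), d,
                                 pattern.window)
            out += w * (d <= r_grid)
    return out * area / (n * (n - 1))


def kendall_concordance(x, y):
    """Kendall tau-b by explicit all-pairs concordance counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            if sx == 0 and sy == 0:
                continue
            if sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - _tie_count(x)) * (n0 - _tie_count(y)))


def _tie_count(v):
    from collections import Counter
    return sum(c * (c - 1) / 2 for c in Counter(v).values())
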