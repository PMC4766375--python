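"""Independent test oracles, deliberately naive and separate from the package.

These re-derive quantities by brute force (Monte-Carlo point sampling,
exhaustive pair classification) so the analytic implementations are checked
against something that shares no code with them.
"""

from __future__ import annotations

import math

import numpy as np


def mc_disk_fraction_in_annulus(
    cell_x: float,
    cell_y: float,
    cell_r: float,
    centre_x: float,
    centre_y: float,
    inner_r: float,
    outer_r: float,
    n_points: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo estimate (and its standard error) of the annulus fraction.

    Uniform points in the cell disk via the polar inverse-CDF; the fraction
    landing in [inner_r, outer_r) estimates the area fraction.
    """
    u = rng.uniform(0.0, 1.0, n_points)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_points)
    r = cell_r * np.sqrt(u)
    px = cell_x + r * np.cos(theta)
    py = cell_y + r * np.sin(theta)
    d = np.hypot(px - centre_x, py - centre_y)
    hits = np.count_nonzero((d >= inner_r) & (d < outer_r))
    f = hits / n_points
    se = math.sqrt(max(f * (1 - f), 1e-12) / n_points)
    return f, se


def mc_lens_area(
    r1: float, r2: float, d: float, n_points: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo lens area: sample in disk 1, count points inside disk 2."""
    u = rng.uniform(0.0, 1.0, n_points)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_points)
    r = r1 * np.sqrt(u)
    px = r * np.cos(theta)
    py = r * np.sin(theta)
    inside = np.hypot(px - d, py) <= r2
    return math.pi * r1**2 * np.count_nonzero(inside) / n_points


def brute_force_kendall_tau_b(x, y) -> float:
    """Tau-b by exhaustive classification of every pair.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2, n1/n2 the
    tied-pair counts in x and y. NaN when either variable is fully tied.
    """
    x = list(x)
    y = list(y)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return math.nan
    return (concordant - discordant) / denom


def brute_force_pearson(x, y) -> float:
    """Pearson r from raw covariance sums, no library calls."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
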