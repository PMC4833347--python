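"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the quantile
oracle enumerates candidate lines instead of solving an LP, and the
volume oracle integrates by Monte-Carlo hit counting instead of using
the closed-form spheroid formula.
"""

from __future__ import annotations

import itertools

import numpy as np


def check_loss(x, y, b0, b1, tau):
    u = np.asarray(y, float) - b0 - b1 * np.asarray(x, float)
    return float(np.sum(u * (tau - (u < 0))))


def pairwise_quantile_fit(x, y, tau):
    """Exhaustive quantile-regression oracle for small n.

    Some optimal check-loss line interpolates at least two data points
    with distinct x (an LP over two free parameters attains its optimum
    at a basic solution), so searching all point-pair lines finds a
    global minimizer.  Returns (intercept, slope, objective).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = (np.inf, 0.0, 0.0)
    for i, j in itertools.combinations(range(x.size), 2):
        if x[i] == x[j]:
            continue
        b1 = (y[j] - y[i]) / (x[j] - x[i])
        b0 = y[i] - b1 * x[i]
        obj = check_loss(x, y, b0, b1, tau)
        if obj < best[0]:
            best = (obj, b0, b1)
    obj, b0, b1 = best
    return b0, b1, obj


def spheroid_volume_mc(length, height, n_points, seed):
    """Monte-Carlo hit-count volume of an ellipsoid with full axes
    (length, height, height), sampled in its bounding box."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-0.5, 0.5, size=(n_points, 3))
    inside = (
        (pts[:, 0] / 0.5) ** 2 + (pts[:, 1] / 0.5) ** 2 + (pts[:, 2] / 0.5) ** 2
    ) <= 1.0
    # unit sphere fraction scaled by the box volume L * H * H
    return inside.mean() * length * height * height


def ols_normal_equations(x, y):
    """Closed-form simple-OLS slope/intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    return y.mean() - slope * x.mean(), slope
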