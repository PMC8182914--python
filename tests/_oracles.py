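"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: dense-sampled
ray integration, exhaustive lattice enumeration, closed forms and full
rank-assignment enumeration.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from mar_evalkit.artifact_sim import FanBeamGeometry, hu_to_mu


def dense_fan_projection(slice_hu, spacing, geom: FanBeamGeometry, oversample: int = 10):
    """Brute-force fan-beam line integrals with ``oversample``-times finer
    sampling than the implementation's half-pixel step."""
    mu = hu_to_mu(slice_hu)
    ny, nx = mu.shape
    dy, dx = spacing
    d = geom.source_center_mm
    R = geom.coverage_radius_mm
    step = 0.5 * min(dx, dy) / oversample
    out = np.zeros((geom.n_views, geom.n_bins))
    cx, cy = (nx - 1) / 2, (ny - 1) / 2

    def sample(fx, fy):
        ix = np.floor(fx).astype(int)
        iy = np.floor(fy).astype(int)
        wx, wy = fx - ix, fy - iy

        def at(ii, jj):
            ok = (jj >= 0) & (jj < nx) & (ii >= 0) & (ii < ny)
            v = np.zeros_like(wx)
            v[ok] = mu[ii[ok], jj[ok]]
            return v

        return (
            at(iy, ix) * (1 - wx) * (1 - wy)
            + at(iy, ix + 1) * wx * (1 - wy)
            + at(iy + 1, ix) * (1 - wx) * wy
            + at(iy + 1, ix + 1) * wx * wy
        )

    for i, b in enumerate(geom.view_angles):
        sx, sy = d * np.cos(b), d * np.sin(b)
        for j, g in enumerate(geom.bin_angles):
            ux, uy = -np.cos(b + g), -np.sin(b + g)
            s_perp = d * np.sin(g)
            h2 = R * R - s_perp * s_perp
            if h2 <= 0:
                continue
            h = np.sqrt(h2)
            tc = d * np.cos(g)
            n = int(2 * h / step) + 1
            dt = 2 * h / n
            t = tc - h + (np.arange(n) + 0.5) * dt
            out[i, j] = sample((sx + t * ux) / dx + cx, (sy + t * uy) / dy + cy).sum() * dt
    return out


def lattice_ball_points(margin: float, spacing=(1.0, 1.0, 1.0)):
    """All integer lattice offsets within Euclidean distance ``margin`` of
    the origin, honoring anisotropic spacing (mm)."""
    dz, dy, dx = spacing
    nz = int(margin / dz) + 1
    ny = int(margin / dy) + 1
    nx = int(margin / dx) + 1
    pts = []
    for k in range(-nz, nz + 1):
        for j in range(-ny, ny + 1):
            for i in range(-nx, nx + 1):
                if (k * dz) ** 2 + (j * dy) ** 2 + (i * dx) ** 2 <= margin**2 + 1e-12:
                    pts.append((k, j, i))
    return pts


def rmse_double_loop(a, b, mask):
    total = 0.0
    n = 0
    nz, ny, nx = a.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if mask[k, j, i]:
                    total += (b[k, j, i] - a[k, j, i]) ** 2
                    n += 1
    return (total / n) ** 0.5


def ols_normal_equations(points):
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    return float(slope), float(intercept)


def anova_sums_of_squares(groups):
    """Textbook one-way ANOVA from explicit sums of squares."""
    from scipy.stats import f as fdist

    groups = [np.asarray(g, dtype=float) for g in groups]
    alldata = np.concatenate(groups)
    grand = alldata.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(alldata) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(fdist.sf(F, df_b, df_w))
    return float(F), p


def mann_whitney_exact_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    pooled ranks to the first sample (no ties assumed)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    n_a, n_b = len(a), len(b)

    # U: count of pairs (x in a, y in b) with x > y
    def u_stat(sa, sb):
        return sum(1 for x in sa for y2 in sb if x > y2)

    u_obs = u_stat(a, b)
    u_min = min(u_obs, n_a * n_b - u_obs)
    count = 0
    total = comb(n_a + n_b, n_a)
    idx = range(n_a + n_b)
    for chosen in combinations(idx, n_a):
        sa = [pooled[i] for i in chosen]
        sb = [pooled[i] for i in idx if i not in chosen]
        u = u_stat(sa, sb)
        if min(u, n_a * n_b - u) <= u_min:
            count += 1
    return u_obs, count / total
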