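"""Independent oracles used to cross-check the package's implementations.

Each oracle deliberately takes a different computational route from the code
it validates: the JZS Bayes factor is computed by marginalising the
noncentral-t likelihood over the Cauchy effect prior (instead of the g-mixture
integral); ring regions come from brute-force per-slice Chebyshev distances
(instead of morphological dilation); the mixed-model marginal goes through the
full N x N observation covariance with tensor-product Gauss-Legendre
quadrature (instead of the precision-matrix closed form with Monte-Carlo).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate, stats


def jzs_bf_oracle(t: float, n: int, r: float) -> float:
    """One-sample JZS BF10 via the noncentral-t route.

    BF10 = int T_nu(t; delta*sqrt(n)) Cauchy(delta; 0, r) d delta / T_nu(t; 0).
    """
    nu = n - 1

    def f(delta: float) -> float:
        return (stats.nct.pdf(t, nu, delta * np.sqrt(n))
                * stats.cauchy.pdf(delta, 0.0, r))

    num, _ = integrate.quad(f, -np.inf, np.inf, epsabs=0.0, epsrel=1e-12,
                            limit=400)
    return num / stats.t.pdf(t, nu)


def ring_oracle(lc: np.ndarray, distance: int,
                exclusion: np.ndarray | None = None) -> np.ndarray:
    """Voxels at exact in-plane Chebyshev distance ``distance`` from the mask."""
    nx, ny, nz = lc.shape
    out = np.zeros_like(lc, dtype=bool)
    for z in range(nz):
        pts = np.argwhere(lc[:, :, z])
        if len(pts) == 0:
            continue
        for i in range(nx):
            for j in range(ny):
                d = np.max(np.abs(pts - (i, j)), axis=1).min()
                if d == distance:
                    out[i, j, z] = True
    if exclusion is not None:
        out &= ~exclusion
    return out


def median_oracle(values: np.ndarray) -> float:
    """Sort-and-pick median with midpoint convention for even counts."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n % 2:
        return float(v[n // 2])
    return float((v[n // 2 - 1] + v[n // 2]) / 2.0)


def quartile_oracle(values: np.ndarray) -> tuple[float, float]:
    """Q1 and Q3 by explicit linear interpolation between order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return float(v[lo] + (h - lo) * (v[hi] - v[lo]))

    return q(0.25), q(0.75)


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def _factor_design(labels: list) -> np.ndarray:
    """Orthonormal sum-to-zero design for a factor (independent copy)."""
    cats = sorted(set(labels))
    a = len(cats)
    Z = np.zeros((len(labels), a))
    for i, lab in enumerate(labels):
        Z[i, cats.index(lab)] = 1.0
    w, v = np.linalg.eigh(np.eye(a) - np.ones((a, a)) / a)
    return Z @ v[:, w > 0.5]


def mixed_model_bf_oracle(df, fixed_scale: float = 0.5,
                          random_scale: float = 1.0, nodes: int = 40) -> float:
    """Interaction BF via the full-covariance marginal and tensor quadrature.

    For each quadrature point g the marginal likelihood is evaluated through
    Sigma = I + sum_b g_b X_b X_b' with the grand mean and error variance
    integrated out analytically; g's are integrated on u = g/(1+g) grids with
    explicit InverseGamma weights.  Practical only for tiny designs.
    """
    y = df["value"].to_numpy(float)
    n_obs = y.size
    x_seq = _factor_design(list(df["sequence"]))
    x_lvl = _factor_design(list(df["level"]))
    x_int = np.einsum("na,nb->nab", x_seq, x_lvl).reshape(n_obs, -1)
    x_sub = _factor_design(list(df["subject"]))
    ones = np.ones(n_obs)

    u, w = leggauss(nodes)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    g_nodes = u / (1.0 - u)
    log_jac = -2.0 * np.log1p(-u)

    def log_invgamma(g: np.ndarray, r: float) -> np.ndarray:
        return (0.5 * np.log(r * r / 2.0) - 0.5 * np.log(np.pi)
                - 1.5 * np.log(g) - r * r / (2.0 * g))

    def log_marginal(batches: list[np.ndarray], scales: list[float]) -> float:
        xxt = [X @ X.T for X in batches]
        logw = [np.log(w) + log_invgamma(g_nodes, r) + log_jac for r in scales]
        total = -np.inf
        for idx in product(range(nodes), repeat=len(batches)):
            sigma = np.eye(n_obs)
            lw = 0.0
            for b, i in enumerate(idx):
                sigma = sigma + g_nodes[i] * xxt[b]
                lw += logw[b][i]
            _, logdet = np.linalg.slogdet(sigma)
            solved = np.linalg.solve(sigma, np.column_stack([y, ones]))
            y_sy = y @ solved[:, 0]
            one_sy = ones @ solved[:, 0]
            one_so = ones @ solved[:, 1]
            ss = y_sy - one_sy ** 2 / one_so
            ll = -0.5 * logdet - 0.5 * np.log(one_so) - 0.5 * (n_obs - 1) * np.log(ss)
            total = np.logaddexp(total, lw + ll)
        return total

    log_full = log_marginal([x_seq, x_lvl, x_int, x_sub],
                            [fixed_scale] * 3 + [random_scale])
    log_red = log_marginal([x_seq, x_lvl, x_sub],
                           [fixed_scale] * 2 + [random_scale])
    return float(np.exp(log_full - log_red))
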