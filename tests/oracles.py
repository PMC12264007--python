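"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the SVR oracle
solves the boxed, equality-constrained dual quadratic program directly
with SLSQP over the paired multipliers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def qp_svr_dual(X: np.ndarray, y: np.ndarray, epsilon: float, C: float):
    """Exact small-scale solve of the paired-multiplier dual program.

    Returns ``(a, a_star, objective)`` minimizing
    ``1/2 sum_ij (a_i - a_i*)(a_j - a_j*) x_i'x_j + eps sum(a + a*)
    - sum y_i (a_i - a_i*)`` subject to the zero-sum and box constraints.
    Multi-started SLSQP; intended for N <= 10, p <= 3 only.
    """
    n = X.shape[0]
    K = X @ X.T

    def loss(z):
        theta = z[:n] - z[n:]
        return 0.5 * theta @ K @ theta + epsilon * z.sum() - y @ theta

    cons = [{"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:])}]
    bounds = [(0.0, C)] * (2 * n)
    best = None
    for trial in range(4):
        rng = np.random.default_rng(trial)
        z0 = rng.uniform(0.0, min(C, 0.1), 2 * n) if trial else np.zeros(2 * n)
        res = minimize(
            loss, z0, method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:n], best.x[n:], float(best.fun)


def pearson_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Direct covariance / SD formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def bh_stepup_enumerate(p: np.ndarray, alpha: float) -> np.ndarray:
    """Exhaustive step-up: largest k with p(k) <= k*alpha/m, reject that prefix."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


def sinusoid_amplitude(series: np.ndarray, freq_hz: float, fs: float, trim: int = 0) -> float:
    """Least-squares amplitude of a sinusoid at a known frequency."""
    y = np.asarray(series, float)
    t = np.arange(y.size) / fs
    design = np.column_stack(
        [np.sin(2 * np.pi * freq_hz * t), np.cos(2 * np.pi * freq_hz * t), np.ones_like(t)]
    )
    sl = slice(trim, y.size - trim if trim else None)
    coef, *_ = np.linalg.lstsq(design[sl], y[sl], rcond=None)
    return float(np.hypot(coef[0], coef[1]))
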