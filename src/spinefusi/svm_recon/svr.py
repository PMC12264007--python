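"""Dual solver for linear epsilon-insensitive SVM regression.

The dual problem is solved over the difference variables
``theta_n = a_n - a_n*`` (valid because complementarity ``a_n a_n* = 0``
holds at any optimum, making the paired-multiplier penalty
``eps * sum(a + a*)`` equal to ``eps * ||theta||_1``)::

    minimize  W(theta) = 1/2 theta' K theta - y' theta + eps * ||theta||_1
    subject to  sum(theta) = 0,  -C <= theta_n <= C

with ``K = X X'``.  An SMO-style scheme updates one seeded, randomized
working pair per iteration (``theta_i += d``, ``theta_j -= d``), which
keeps the equality constraint satisfied exactly; the one-dimensional
subproblem is a piecewise quadratic (breakpoints where a theta crosses
zero) minimized in closed form on each segment.  Convergence is declared
when the spread of the per-observation KKT intervals for the equality
multiplier drops below tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SvmModel", "train_svr", "predict"]

logger = logging.getLogger(__name__)

_ZERO = 1e-12


@dataclass
class SvmModel:
    """Converged (or best-effort) epsilon-SVR model.

    ``beta = sum_n (a_n - a_n*) x_n`` is the primal weight vector; the
    bias is recovered from the KKT equalities of the free support
    vectors.  ``training_objective`` is the primal value
    ``1/2 ||beta||^2 + C sum(xi + xi*)`` and ``dual_objective`` the
    minimized dual loss ``L(a)``; at the optimum ``J = -L``.
    """

    beta: np.ndarray
    bias: float
    alphas: np.ndarray
    alphas_star: np.ndarray
    epsilon: float
    C: float
    xi: np.ndarray
    xi_star: np.ndarray
    training_objective: float
    dual_objective: float
    n_train: int
    seed: int
    converged: bool
    kkt_violation: float
    n_iter: int
    support_vectors: np.ndarray = field(repr=False, default=None)

    @property
    def theta(self) -> np.ndarray:
        return self.alphas - self.alphas_star


def _kkt_intervals(theta: np.ndarray, grad: np.ndarray, eps: float, C: float):
    """Per-observation interval [lo, hi] that -b must inhabit at optimality."""
    lo = np.where(theta > _ZERO, grad + eps, grad - eps)
    hi = np.where(theta < -_ZERO, grad - eps, grad + eps)
    at_zero = np.abs(theta) <= _ZERO
    lo[at_zero] = grad[at_zero] - eps
    hi[at_zero] = grad[at_zero] + eps
    at_top = theta >= C - _ZERO
    at_bot = theta <= -C + _ZERO
    lo[at_top] = grad[at_top] + eps
    hi[at_top] = np.inf
    lo[at_bot] = -np.inf
    hi[at_bot] = grad[at_bot] - eps
    return lo, hi


def _pair_step(theta, grad, K, i, j, eps, C):
    """Optimal d for theta_i += d, theta_j -= d (piecewise quadratic)."""
    eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
    eta = max(eta, 1e-14)
    g = grad[i] - grad[j]
    lo = max(-C - theta[i], theta[j] - C)
    hi = min(C - theta[i], theta[j] + C)
    if hi <= lo:
        return 0.0

    def phi(d):
        return (
            0.5 * eta * d * d
            + g * d
            + eps * (abs(theta[i] + d) - abs(theta[i]) + abs(theta[j] - d) - abs(theta[j]))
        )

    brk = sorted({lo, hi, -theta[i], theta[j]})
    brk = [b for b in brk if lo <= b <= hi]
    cands = list(brk)
    for a, b in zip(brk[:-1], brk[1:]):
        mid = 0.5 * (a + b)
        s_i = np.sign(theta[i] + mid)
        s_j = np.sign(theta[j] - mid)
        d = -(g + eps * (s_i - s_j)) / eta
        if a < d < b:
            cands.append(d)
    best_d, best_v = 0.0, 0.0
    for d in cands:
        v = phi(d)
        if v < best_v:
            best_v, best_d = v, d
    return best_d


def train_svr(
    X: np.ndarray,
    y: np.ndarray,
    epsilon: float | None = None,
    C: float = 1.0,
    tol: float = 1e-6,
    max_passes: int | None = None,
    seed: int = 0,
    random_pair_prob: float = 0.05,
) -> SvmModel:
    """Fit the dual epsilon-SVR on training rows ``X`` and targets ``y``.

    ``epsilon=None`` uses the heuristic ``0.1 * SD(y)``.  ``max_passes``
    bounds the number of pair updates (default ``max(200 * N, 2000)``).  Working
    pairs are chosen as the maximally KKT-violating pair, replaced with
    probability ``random_pair_prob`` by a random violating index for the
    seeded stochastic flavor.  Non-convergence returns the model with
    ``converged=False`` and a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (N, p) and y (N,)")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in training data")
    if C <= 0:
        raise ValueError("C must be > 0")
    n = y.size
    if epsilon is None:
        epsilon = 0.1 * float(np.std(y))
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    max_iter = max(200 * n, 2000) if max_passes is None else int(max_passes)

    K = X @ X.T
    diag = np.ascontiguousarray(np.diag(K))
    theta = np.zeros(n)
    grad = -y.copy()  # grad of smooth part: K theta - y
    rng = np.random.default_rng(seed)

    violation = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        lo, hi = _kkt_intervals(theta, grad, epsilon, C)
        i = int(np.argmax(lo))
        violation = lo[i] - float(np.min(hi))
        if violation <= tol:
            break
        # second-order partner: maximal estimated objective decrease
        diff = lo[i] - hi
        cand = diff > 0
        cand[i] = False
        eta = np.maximum(diag[i] + diag - 2.0 * K[:, i], 1e-14)
        gains = np.where(cand, diff * diff / eta, -np.inf)
        j = int(np.argmax(gains))
        if rng.random() < random_pair_prob:
            choices = np.flatnonzero(cand)
            if choices.size:
                j = int(rng.choice(choices))
        d = _pair_step(theta, grad, K, i, j, epsilon, C)
        if d == 0.0:
            # the gain estimate ignores the L1 kink; fall back to the
            # classical maximal-violating partner before declaring a stall
            j = int(np.argmin(hi))
            d = _pair_step(theta, grad, K, i, j, epsilon, C)
            if d == 0.0:
                break  # float-precision floor on the maximal violating pair
        theta[i] += d
        theta[j] -= d
        grad += d * (K[:, i] - K[:, j])

    lo, hi = _kkt_intervals(theta, grad, epsilon, C)
    violation = float(np.max(lo) - np.min(hi))
    converged = violation <= tol
    if not converged:
        logger.warning(
            "SVR did not converge in %d iterations (KKT violation %.3g > %.3g)",
            max_iter, violation, tol,
        )

    # bias: average over free support vectors; fall back to interval midpoint
    free = (np.abs(theta) > _ZERO) & (np.abs(theta) < C - _ZERO)
    if free.any():
        bias = float(np.mean(-(grad[free] + epsilon * np.sign(theta[free]))))
    else:
        bias = float(-0.5 * (np.max(lo) + np.min(hi)))

    beta = X.T @ theta
    resid = y - (X @ beta + bias)
    xi = np.maximum(resid - epsilon, 0.0)
    xi_star = np.maximum(-resid - epsilon, 0.0)
    primal = 0.5 * float(beta @ beta) + C * float(np.sum(xi + xi_star))
    dual = (
        0.5 * float(theta @ (K @ theta))
        + epsilon * float(np.sum(np.abs(theta)))
        - float(y @ theta)
    )

    alphas = np.maximum(theta, 0.0)
    alphas_star = np.maximum(-theta, 0.0)
    return SvmModel(
        beta=beta,
        bias=bias,
        alphas=alphas,
        alphas_star=alphas_star,
        epsilon=float(epsilon),
        C=float(C),
        xi=xi,
        xi_star=xi_star,
        training_objective=primal,
        dual_objective=dual,
        n_train=n,
        seed=seed,
        converged=converged,
        kkt_violation=violation,
        n_iter=it,
        support_vectors=X,
    )


def predict(model: SvmModel, X: np.ndarray, form: str = "primal") -> np.ndarray:
    """``F(x) = x' beta + b``; the dual form sums over support vectors.

    Both forms agree to numerical precision because
    ``beta = sum_n (a_n - a_n*) x_n`` exactly as computed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.beta.size:
        raise ValueError(
            f"X must be 2D with {model.beta.size} columns, got {X.shape}"
        )
    if form == "primal":
        return X @ model.beta + model.bias
    if form == "dual":
        if model.support_vectors is None:
            raise ValueError("model carries no training rows for dual prediction")
        theta = model.theta
        sv = np.abs(theta) > 0
        return (X @ model.support_vectors[sv].T) @ theta[sv] + model.bias
    raise ValueError(f"unknown form {form!r}")
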