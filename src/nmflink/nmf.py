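"""Non-negative matrix factorization by multiplicative updates.

Two cost functions are supported for A ~= W @ H with entrywise
non-negative factors: the squared Frobenius distance ||A - WH||_F^2 and
the generalized Kullback-Leibler divergence
D(A || WH) = sum(A * log(A / WH) - A + WH), with 0*log(0) := 0.
Both use the classical alternating multiplicative update rules, which
keep the factors non-negative and never increase the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import derive_rng

__all__ = ["Factorization", "factorize_frobenius", "factorize_kl"]

_EPS = 1e-12  # division guard and entry floor


@dataclass(frozen=True)
class Factorization:
    w: np.ndarray  # (n, k), >= 0
    h: np.ndarray  # (k, m), >= 0
    objective_trace: tuple
    converged: bool
    iterations: int

    @property
    def reconstruction(self) -> np.ndarray:
        return self.w @ self.h


def _validate(a: np.ndarray, k: int, max_iter: int) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    if np.any(a < 0):
        raise ValueError("input matrix must be entrywise non-negative")
    if not 1 <= k <= min(a.shape):
        raise ValueError(f"k must be in [1, {min(a.shape)}], got {k}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    return a


def _init(a: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = derive_rng(seed, "nmf-init")
    scale = np.sqrt(max(a.mean(), _EPS) / k)
    w = rng.uniform(0.0, 1.0, size=(a.shape[0], k)) * scale
    h = rng.uniform(0.0, 1.0, size=(k, a.shape[1])) * scale
    return np.maximum(w, _EPS), np.maximum(h, _EPS)


def _frobenius_objective(a: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    return float(np.linalg.norm(a - w @ h) ** 2)


def _kl_objective(a: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    wh = w @ h + _EPS
    pos = a > 0
    term = np.zeros_like(a)
    # log difference, not log of the ratio: a/wh can underflow for subnormal a
    term[pos] = a[pos] * (np.log(a[pos]) - np.log(wh[pos]))
    return float(np.sum(term - a + wh))


def factorize_frobenius(
    a: np.ndarray, k: int, max_iter: int = 500, rel_tol: float = 1e-6, seed: int = 0
) -> Factorization:
    """Minimize ||A - WH||_F^2 by multiplicative updates.

    Stops at max_iter or when the relative objective decrease falls below
    rel_tol. Fully determined by (a, k, seed).
    """
    a = _validate(a, k, max_iter)
    w, h = _init(a, k, seed)
    trace = [_frobenius_objective(a, w, h)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h *= (w.T @ a) / (w.T @ w @ h + _EPS)
        h = np.maximum(h, _EPS)
        w *= (a @ h.T) / (w @ (h @ h.T) + _EPS)
        w = np.maximum(w, _EPS)
        obj = _frobenius_objective(a, w, h)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj < rel_tol * max(abs(prev), _EPS):
            converged = True
            break
    return Factorization(
        w=w, h=h, objective_trace=tuple(trace), converged=converged, iterations=it
    )


def factorize_kl(
    a: np.ndarray, k: int, max_iter: int = 500, rel_tol: float = 1e-6, seed: int = 0
) -> Factorization:
    """Minimize the generalized KL divergence D(A || WH) by multiplicative
    updates; divisions are epsilon-guarded so zero rows/columns stay finite."""
    a = _validate(a, k, max_iter)
    w, h = _init(a, k, seed)
    trace = [_kl_objective(a, w, h)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wh = w @ h + _EPS
        h *= (w.T @ (a / wh)) / (w.sum(axis=0)[:, None] + _EPS)
        h = np.maximum(h, _EPS)
        wh = w @ h + _EPS
        w *= ((a / wh) @ h.T) / (h.sum(axis=1)[None, :] + _EPS)
        w = np.maximum(w, _EPS)
        obj = _kl_objective(a, w, h)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj < rel_tol * max(abs(prev), _EPS):
            converged = True
            break
    return Factorization(
        w=w, h=h, objective_trace=tuple(trace), converged=converged, iterations=it
    )
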