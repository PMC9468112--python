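"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A self-contained (mu/mu_w, lambda)-CMA-ES minimizer with cumulative
step-size adaptation and rank-one plus rank-mu covariance updates — the
standard derivative-free strategy used here to avoid the local minima of
the pose-similarity landscape.  Deterministic given a seed; box bounds are
handled by evaluating the clipped candidate plus a quadratic out-of-bounds
penalty, so the returned best is always feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["cma_es_minimize", "CMATrace"]


@dataclass
class CMATrace:
    """Per-generation record of a CMA-ES run."""

    best_f: list = field(default_factory=list)  # best-seen objective, non-increasing
    sigma: list = field(default_factory=list)
    evaluations: int = 0
    stopped: str = "budget"


def cma_es_minimize(
    objective,
    x0,
    sigma0,
    bounds=None,
    seed: int = 0,
    max_evals: int = 1500,
    popsize: int | None = None,
    ftol_rel: float = 1e-3,
    stagnation_gens: int = 20,
):
    """Minimize ``objective`` over R^n starting from ``x0``.

    Parameters
    ----------
    sigma0 : scalar or per-coordinate initial step (vector scales are folded
        into the variable scaling, so anisotropic search ranges are natural).
    bounds : optional (lower, upper) arrays containing ``x0``.
    max_evals : evaluation budget; with a budget of 1 the start point is
        evaluated and returned unchanged.
    ftol_rel : relative best-objective stagnation tolerance — the run stops
        once the best value improves by less than this fraction over
        ``stagnation_gens`` consecutive generations.

    Returns ``(best_x, trace)``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    scales = np.broadcast_to(np.asarray(sigma0, dtype=float), (n,)).copy()
    if np.any(scales <= 0):
        raise ValueError("sigma0 must be positive")
    if bounds is not None:
        lb = np.asarray(bounds[0], dtype=float)
        ub = np.asarray(bounds[1], dtype=float)
        if np.any(x0 < lb) or np.any(x0 > ub):
            raise ValueError("bounds must contain x0")
    else:
        lb = ub = None

    def eval_x(x):
        if lb is None:
            return float(objective(x)), x
        xc = np.clip(x, lb, ub)
        pen = float(np.sum(((x - xc) / scales) ** 2))
        return float(objective(xc)) + pen, xc

    f0, x0c = eval_x(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at x0")
    trace = CMATrace()
    trace.evaluations = 1
    best_x, best_f = x0c.copy(), f0
    trace.best_f.append(best_f)
    if max_evals <= 1:
        trace.stopped = "budget"
        return best_x, trace

    # strategy parameters (Hansen's defaults)
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    rng = np.random.default_rng(seed)
    # search in the normalized space y = (x - x0)/scales
    m = np.zeros(n)
    sigma = 1.0
    C = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    B, D = np.eye(n), np.ones(n)
    eigen_stale = 0
    stall = 0
    last_best = best_f

    while trace.evaluations < max_evals:
        if eigen_stale == 0:
            C = (C + C.T) / 2
            d2, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(d2, 1e-20))
            eigen_stale = max(1, int(1 / (10 * n * (c1 + cmu)) / lam))
        eigen_stale -= 1

        k = min(lam, max_evals - trace.evaluations)
        Z = rng.standard_normal((lam, n))[:k]
        Y = (B * D) @ Z.T  # n x k
        xs = x0 + scales * (m[:, None] + sigma * Y).T
        fs = np.empty(k)
        xcs = []
        for i in range(k):
            fs[i], xc = eval_x(xs[i])
            xcs.append(xc)
        trace.evaluations += k
        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xcs[order[0]].copy()
        trace.best_f.append(best_f)
        trace.sigma.append(sigma)
        if k < lam:
            trace.stopped = "budget"
            break

        sel = order[:mu]
        ymean = (Y[:, sel] * w).sum(axis=1)
        m = m + sigma * ymean

        # step-size control
        Cinvsqrt_y = B @ ((B.T @ ymean) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * Cinvsqrt_y
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chiN - 1))

        # covariance adaptation
        hsig = np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * trace.evaluations / lam)) < (
            1.4 + 2 / (n + 1)
        ) * chiN
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * ymean
        rank1 = np.outer(pc, pc)
        rankmu = (Y[:, sel] * w) @ Y[:, sel].T
        C = (1 - c1 - cmu) * C + c1 * (rank1 + (1 - hsig) * cc * (2 - cc) * C) + cmu * rankmu

        # stagnation stop on the best-seen objective
        denom = max(abs(last_best), 1e-12)
        if (last_best - best_f) / denom < ftol_rel:
            stall += 1
            if stall >= stagnation_gens:
                trace.stopped = "stagnation"
                break
        else:
            stall = 0
            last_best = best_f
        if sigma < 1e-12:
            trace.stopped = "sigma-collapse"
            break

    return best_x, trace
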