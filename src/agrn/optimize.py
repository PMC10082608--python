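"""Sequential model-based (Bayesian) minimization over a box.

A small Gaussian-process optimizer in the usual mold: an initial design
(optionally anchored at a caller-supplied point), then expected-improvement
proposals from a GP surrogate fitted to the evaluations so far. Candidates
for the acquisition step are random draws from the box; with a few dozen
objective calls on a 2-D search space this is entirely adequate.

Everything is deterministic given the supplied generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

__all__ = ["OptimizationResult", "minimize_smbo"]


@dataclass(frozen=True)
class OptimizationResult:
    x: np.ndarray
    fun: float
    x_iters: np.ndarray
    func_vals: np.ndarray


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def minimize_smbo(
    objective,
    bounds: list[tuple[float, float]],
    n_calls: int,
    rng: np.random.Generator,
    anchor: np.ndarray | None = None,
    n_initial: int | None = None,
    n_candidates: int = 512,
) -> OptimizationResult:
    """Minimize ``objective`` over a box with a GP surrogate.

    Parameters
    ----------
    objective
        Callable mapping a point (1-D array of len(bounds)) to a scalar.
    bounds
        Per-dimension (low, high) limits; a dimension with low == high is
        held fixed. If every dimension is collapsed the single feasible
        point is returned after one evaluation.
    n_calls
        Total number of objective evaluations, initial design included.
    rng
        Source of randomness for the design and candidate draws.
    anchor
        Optional point guaranteed to be evaluated first, so the returned
        minimum is never worse than the anchor's objective value.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi < lo):
        raise ValueError("each bound must satisfy low <= high")
    span = hi - lo
    fixed = span == 0.0

    if n_calls < 1:
        raise ValueError("n_calls must be at least 1")

    def draw(n: int) -> np.ndarray:
        pts = lo + rng.random((n, len(bounds))) * span
        return pts

    xs: list[np.ndarray] = []
    if anchor is not None:
        anchor = np.clip(np.asarray(anchor, dtype=float), lo, hi)
        xs.append(anchor)
    if np.all(fixed):
        xs = [lo.copy()]
        fv = float(objective(lo.copy()))
        return OptimizationResult(x=lo.copy(), fun=fv,
                                  x_iters=np.array([lo]), func_vals=np.array([fv]))

    if n_initial is None:
        n_initial = max(4, n_calls // 4)
    n_initial = min(n_initial, n_calls)
    while len(xs) < n_initial:
        xs.append(draw(1)[0])
    xs = xs[:n_calls]
    ys = [float(objective(x)) for x in xs]

    while len(xs) < n_calls:
        X = np.array(xs)
        y = np.array(ys)
        # normalize inputs to the unit box for GP conditioning
        Xn = (X - lo) / np.where(fixed, 1.0, span)
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(length_scale=np.full(len(bounds), 0.25), nu=2.5,
                     length_scale_bounds=(1e-3, 1e2)),
            alpha=1e-10 + 1e-8 * float(np.var(y)),
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xn, y)
        cand = draw(n_candidates)
        cand_n = (cand - lo) / np.where(fixed, 1.0, span)
        mu, sigma = gp.predict(cand_n, return_std=True)
        ei = _expected_improvement(mu, sigma, float(np.min(y)))
        nxt = cand[int(np.argmax(ei))]
        xs.append(nxt)
        ys.append(float(objective(nxt)))
    best = int(np.argmin(ys))
    return OptimizationResult(
        x=xs[best].copy(), fun=float(ys[best]),
        x_iters=np.array(xs), func_vals=np.array(ys),
    )
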