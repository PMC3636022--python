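"""Covariance-matrix-adaptation evolution strategy (CMA-ES).

A derivative-free stochastic optimizer for non-convex, noisy continuous
problems.  This is the standard (mu/mu_w, lambda)-CMA-ES with cumulative
step-size adaptation and rank-one plus rank-mu covariance updates, following
Hansen's reference formulation.  Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAES", "minimize", "CMAResult"]


@dataclass
class CMAResult:
    x: np.ndarray            # best-so-far solution
    fun: float               # its objective value
    n_evals: int
    trace: np.ndarray        # best-so-far objective per generation
    x_mean: np.ndarray       # final distribution mean


class CMAES:
    """Ask/tell interface.

    Parameters
    ----------
    x0 : initial mean.
    sigma0 : initial global step size (same scale as x0 coordinates).
    popsize : lambda; default 4 + floor(3 ln n).
    seed : RNG seed.
    """

    def __init__(self, x0, sigma0: float, popsize: int | None = None,
                 seed: int | None = None):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = len(self.mean)
        self.sigma = float(sigma0)
        self.lam = popsize or (4 + int(3 * np.log(self.n)))
        self.rng = np.random.default_rng(seed)

        mu = self.lam // 2
        w = np.log(self.lam / 2 + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu = mu
        self.mueff = 1.0 / np.sum(self.weights**2)

        n, mueff = self.n, self.mueff
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.invsqrtC = np.eye(n)
        self.eigen_stale = 0
        self.n_evals = 0
        self.generation = 0
        self.best_x = self.mean.copy()
        self.best_f = np.inf
        self._pending = None

    def ask(self) -> np.ndarray:
        """Sample lambda candidate solutions, shape (lambda, n)."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T          # B diag(D) z
        self._pending = y
        return self.mean + self.sigma * y

    def tell(self, solutions: np.ndarray, fitness) -> None:
        fitness = np.asarray(fitness, dtype=float)
        if not np.all(np.isfinite(fitness)):
            raise FloatingPointError("non-finite objective value in CMA-ES")
        order = np.argsort(fitness)
        self.n_evals += self.lam
        self.generation += 1
        if fitness[order[0]] < self.best_f:
            self.best_f = float(fitness[order[0]])
            self.best_x = np.array(solutions[order[0]], dtype=float)

        y = (np.asarray(solutions)[order[:self.mu]] - self.mean) / self.sigma
        y_w = self.weights @ y
        self.mean = self.mean + self.sigma * y_w

        self.ps = (1 - self.cs) * self.ps + \
            np.sqrt(self.cs * (2 - self.cs) * self.mueff) * (self.invsqrtC @ y_w)
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * self.generation)) / self.chiN
                < 1.4 + 2 / (self.n + 1))
        self.pc = (1 - self.cc) * self.pc + \
            hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_w

        c1a = self.c1 * (1 - (1 - hsig**2) * self.cc * (2 - self.cc))
        self.C = (1 - c1a - self.cmu) * self.C \
            + self.c1 * np.outer(self.pc, self.pc) \
            + self.cmu * (y.T * self.weights) @ y
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))

        self.eigen_stale += 1
        if self.eigen_stale > max(1, int(1 / (10 * self.n * (self.c1 + self.cmu)) / self.lam)):
            self._update_eigen()

    def _update_eigen(self):
        self.eigen_stale = 0
        self.C = (self.C + self.C.T) / 2
        d2, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d2, 1e-20))
        self.invsqrtC = (self.B / self.D) @ self.B.T


def minimize(f, x0, sigma0: float, popsize: int | None = None,
             generations: int = 100, seed: int | None = None,
             callback=None) -> CMAResult:
    """Minimize ``f`` with CMA-ES for a fixed number of generations.

    Keeps elitist best-so-far bookkeeping, so the reported objective trace is
    non-increasing even on noisy landscapes.
    """
    es = CMAES(x0, sigma0, popsize=popsize, seed=seed)
    trace = np.empty(generations)
    for g in range(generations):
        X = es.ask()
        es.tell(X, [f(x) for x in X])
        trace[g] = es.best_f
        if callback is not None:
            callback(es)
    return CMAResult(x=es.best_x, fun=es.best_f, n_evals=es.n_evals,
                     trace=trace, x_mean=es.mean.copy())
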