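"""General-intelligence factor extraction via a bifactor model.

Ten cognitive test scores are modeled as

    x = Λ_g · g + Λ_k · f_k(t) + ε,

where every test loads on the general factor ``g`` and on exactly one of a
small number of orthogonal group factors. The model is fit by maximum
likelihood on the correlation matrix of the (internally standardized)
scores, and per-subject g scores are obtained with the regression
(Thurstone) method and standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["BifactorFit", "fit_bifactor", "variance_explained_by_g"]

_PSI_FLOOR = 0.005


class ConvergenceError(RuntimeError):
    pass


@dataclass
class BifactorFit:
    """Fitted bifactor model and derived per-subject g scores."""

    loadings_g: np.ndarray          # (n_tests,)
    loadings_group: np.ndarray      # (n_tests,) — loading on the test's group
    group_assignment: np.ndarray    # (n_tests,)
    uniquenesses: np.ndarray        # (n_tests,)
    g_scores: np.ndarray            # (n_subjects,), standardized
    n_iterations: int
    discrepancy: float

    @property
    def n_groups(self) -> int:
        return int(self.group_assignment.max()) + 1

    def loading_matrix(self) -> np.ndarray:
        """(n_tests, 1 + n_groups) structured loading matrix; column 0 is g."""
        n_tests = len(self.loadings_g)
        lam = np.zeros((n_tests, 1 + self.n_groups))
        lam[:, 0] = self.loadings_g
        lam[np.arange(n_tests), 1 + self.group_assignment] = self.loadings_group
        return lam

    def implied_correlation(self) -> np.ndarray:
        lam = self.loading_matrix()
        return lam @ lam.T + np.diag(self.uniquenesses)


def _implied(lg, lk, psi, assignment, n_groups):
    n = len(lg)
    lam = np.zeros((n, 1 + n_groups))
    lam[:, 0] = lg
    lam[np.arange(n), 1 + assignment] = lk
    return lam @ lam.T + np.diag(psi)


def _discrepancy(theta, s, assignment, n_groups):
    n = s.shape[0]
    lg = theta[:n]
    lk = theta[n:2 * n]
    psi = np.exp(theta[2 * n:])
    sigma = _implied(lg, lk, psi, assignment, n_groups)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    inv = np.linalg.inv(sigma)
    return logdet + np.trace(s @ inv)


def fit_bifactor(
    scores: np.ndarray,
    group_assignment: np.ndarray,
    seed: int = 0,
    n_starts: int = 3,
    max_iter: int = 2000,
) -> BifactorFit:
    """Fit the bifactor model by maximum likelihood and score subjects.

    ``scores`` is subjects × tests (standardized internally, so affine
    rescaling of any column leaves the result unchanged);
    ``group_assignment`` maps each test to one group factor. Requires ≥ 50
    subjects. Uniquenesses are floored at 0.005 (Heywood protection, with a
    warning); non-convergence of every start raises with diagnostics.
    """
    scores = np.asarray(scores, float)
    n_sub, n_tests = scores.shape
    if n_sub < 50:
        raise ValueError("need at least 50 subjects for a stable fit")
    assignment = np.asarray(group_assignment, int)
    if assignment.shape != (n_tests,):
        raise ValueError("one group assignment per test is required")
    n_groups = int(assignment.max()) + 1

    sd = scores.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant test column")
    x = (scores - scores.mean(axis=0)) / sd
    s = (x.T @ x) / (n_sub - 1)

    rng = np.random.default_rng(seed)
    bounds = ([(-1.5, 1.5)] * (2 * n_tests)
              + [(np.log(_PSI_FLOOR), np.log(4.0))] * n_tests)
    best = None
    diagnostics = []
    for start in range(n_starts):
        jitter = 0.0 if start == 0 else 0.1
        theta0 = np.concatenate([
            np.full(n_tests, 0.6) + jitter * rng.standard_normal(n_tests),
            np.full(n_tests, 0.3) + jitter * rng.standard_normal(n_tests),
            np.log(np.full(n_tests, 0.4))
            + jitter * rng.standard_normal(n_tests),
        ])
        res = optimize.minimize(
            _discrepancy, theta0, args=(s, assignment, n_groups),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
        )
        diagnostics.append((res.success, res.nit, res.fun))
        if res.success and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise ConvergenceError(f"bifactor fit failed: {diagnostics}")

    lg = best.x[:n_tests]
    lk = best.x[n_tests:2 * n_tests]
    psi = np.exp(best.x[2 * n_tests:])
    if np.any(psi <= _PSI_FLOOR * 1.01):
        warnings.warn("uniqueness at Heywood floor; interpret with care",
                      stacklevel=2)
    # sign identification: g and each group factor load positively on average
    if lg.sum() < 0:
        lg = -lg
    for k in range(n_groups):
        mask = assignment == k
        if lk[mask].sum() < 0:
            lk[mask] = -lk[mask]

    lam = np.zeros((n_tests, 1 + n_groups))
    lam[:, 0] = lg
    lam[np.arange(n_tests), 1 + assignment] = lk
    sigma = lam @ lam.T + np.diag(psi)
    # regression (Thurstone) factor scores: F = X Σ⁻¹ Λ
    factor_scores = x @ np.linalg.solve(sigma, lam)
    g = factor_scores[:, 0]
    g_sd = g.std()
    if g_sd == 0:
        raise ConvergenceError("degenerate g scores (zero variance)")
    g = (g - g.mean()) / g_sd

    return BifactorFit(
        loadings_g=lg, loadings_group=lk, group_assignment=assignment,
        uniquenesses=psi, g_scores=g, n_iterations=int(best.nit),
        discrepancy=float(best.fun),
    )


def variance_explained_by_g(fit: BifactorFit) -> float:
    """Percent of common variance carried by g: Σλ_g² / Σ(all λ²) × 100."""
    common_g = np.sum(fit.loadings_g**2)
    common_all = common_g + np.sum(fit.loadings_group**2)
    if common_all == 0:
        raise ValueError("no common variance in fit")
    return float(100.0 * common_g / common_all)
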