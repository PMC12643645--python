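"""Conditional logistic regression for time-stratified case-crossover strata.

Each stratum contributes one case day and its matched control days; the
conditional likelihood for stratum s with case row x_case is

    P(case | stratum) = exp(x_case . beta) / sum_d exp(x_d . beta),

a softmax over the stratum's days. Stratum-level intercepts cancel, so no
intercept column is ever included. The likelihood is maximized by Newton's
method with step-halving, with the covariance taken from the inverse
observed information at the optimum.

All computations are vectorized over strata via segment reductions, so fits
on tens of thousands of strata take well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SeparationError(RuntimeError):
    """Raised when the conditional likelihood has no finite maximizer.

    Happens under complete separation, e.g. when the case day carries the
    stratum-maximal exposure in every stratum; coefficients diverge and any
    reported estimate would be an artifact of the stopping rule.
    """


@dataclass
class StratumData:
    """Long-format stacked design for a set of strata.

    Rows must be grouped by stratum (contiguous blocks). ``case`` flags
    exactly one row per stratum.
    """

    X: np.ndarray            # (n_rows, p)
    case: np.ndarray         # (n_rows,) bool
    stratum: np.ndarray      # (n_rows,) int labels, contiguous blocks
    starts: np.ndarray = field(init=False)  # first row of each stratum

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.case = np.asarray(self.case, dtype=bool)
        self.stratum = np.asarray(self.stratum)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite design entries")
        change = np.flatnonzero(self.stratum[1:] != self.stratum[:-1]) + 1
        self.starts = np.concatenate([[0], change])
        n_case = np.add.reduceat(self.case.astype(int), self.starts)
        if not np.all(n_case == 1):
            raise ValueError("each stratum must contain exactly one case day")
        sizes = np.diff(np.concatenate([self.starts, [len(self.stratum)]]))
        if np.any(sizes < 2):
            raise ValueError("each stratum needs at least one control day")

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit."""

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_strata: int
    converged: bool
    iterations: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def _segment_softmax(eta: np.ndarray, starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum softmax weights and log-sum-exp, numerically stabilized."""
    seg_max = np.maximum.reduceat(eta, starts)
    centered = eta - np.repeat(seg_max, np.diff(np.concatenate([starts, [len(eta)]])))
    ex = np.exp(centered)
    seg_sum = np.add.reduceat(ex, starts)
    sizes = np.diff(np.concatenate([starts, [len(eta)]]))
    w = ex / np.repeat(seg_sum, sizes)
    lse = seg_max + np.log(seg_sum)
    return w, lse


def negloglik(beta: np.ndarray, data: StratumData,
              hessian: bool = False):
    """Negative conditional log-likelihood, analytic gradient, optional Hessian.

    value = -sum_s [x_case . beta - log sum_d exp(x_d . beta)]
    grad  = -sum_s [x_case - sum_d w_d x_d]          (w = softmax weights)
    hess  =  sum_s [sum_d w_d x_d x_d' - x_bar_s x_bar_s']
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = data.X @ beta
    w, lse = _segment_softmax(eta, data.starts)
    nll = float(np.sum(lse) - eta[data.case].sum())
    wx = w[:, None] * data.X
    sizes = np.diff(np.concatenate([data.starts, [len(eta)]]))
    xbar = np.add.reduceat(wx, data.starts, axis=0)  # (n_strata, p)
    grad = xbar.sum(axis=0) - data.X[data.case].sum(axis=0)
    if not hessian:
        return nll, grad
    H = data.X.T @ wx - xbar.T @ xbar
    return nll, grad, H


def fit(data: StratumData, init: np.ndarray | None = None,
        tol: float = 1e-10, grad_tol: float = 1e-6, max_iter: int = 100,
        separation_bound: float = 15.0) -> FitResult:
    """Newton maximization of the conditional likelihood.

    Converged when the relative log-likelihood change drops below ``tol``
    and the gradient's max absolute entry below ``grad_tol``.  A coefficient
    exceeding ``separation_bound`` in magnitude with a still-nonzero gradient
    triggers :class:`SeparationError` instead of returning a runaway
    estimate. Non-positive-definite Hessians fall back to a
    gradient-descent step.
    """
    p = data.n_params
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    nll, grad, H = negloglik(beta, data, hessian=True)
    n_iter = 0
    converged = False
    step_cap = 5.0  # trust-region-style cap; flat directions move gradually
    for n_iter in range(1, max_iter + 1):
        # ridge-damped Newton: a tiny relative ridge keeps near-singular
        # information matrices (weakly identified spline corners) tractable
        ridge = 1e-10 * max(np.trace(H) / p, 1.0)
        step = None
        for _ in range(12):
            try:
                step = np.linalg.solve(H + ridge * np.eye(p), grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 100.0, 1e-8)
        if step is None:
            step = grad / max(np.linalg.norm(grad), 1.0)
        norm = np.linalg.norm(step)
        if norm > step_cap:
            step = step * (step_cap / norm)
        # step-halving line search on the descent direction
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            cand_nll, cand_grad, cand_H = negloglik(cand, data, hessian=True)
            if cand_nll <= nll + 1e-14:
                break
            t *= 0.5
        rel_change = abs(nll - cand_nll) / max(abs(nll), 1.0)
        beta, nll, grad, H = cand, cand_nll, cand_grad, cand_H
        if rel_change < tol and np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
    if np.max(np.abs(beta)) > separation_bound:
        raise SeparationError(
            f"diverging coefficient (|beta| > {separation_bound}); "
            "likely complete separation")
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    vcov = (vcov + vcov.T) / 2.0
    return FitResult(beta=beta, vcov=vcov, loglik=-nll, n_strata=data.n_strata,
                     converged=converged, iterations=n_iter)


def aic(result: FitResult) -> float:
    """Akaike information criterion, 2k - 2 loglik."""
    if not result.converged:
        raise ValueError("AIC requires a converged fit")
    return 2.0 * len(result.beta) - 2.0 * result.loglik


def select_df(design_builder, candidate_dfs: list, **fit_kwargs):
    """Fit one model per candidate df and return (best_df, AIC table).

    ``design_builder(df)`` must return the :class:`StratumData` for that
    candidate. Ties break toward the smaller df; candidates that fail to
    fit are excluded (all failing raises).
    """
    rows = []
    for df in candidate_dfs:
        try:
            res = fit(design_builder(df), **fit_kwargs)
            rows.append((df, aic(res), res))
        except (SeparationError, ValueError, np.linalg.LinAlgError):
            continue
    if not rows:
        raise RuntimeError("no candidate df produced a converged fit")
    rows.sort(key=lambda r: (r[1], _df_order(r[0])))
    table = [{"df": r[0], "aic": r[1]} for r in sorted(rows, key=lambda r: _df_order(r[0]))]
    return rows[0][0], table


def _df_order(df) -> float:
    # "linear" sorts before any spline df for tie-breaking
    return 0.0 if df == "linear" else float(df)
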