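"""Least-angle regression with the lasso modification, from scratch.

The solver traces the piecewise-linear lasso coefficient path: starting
from the null model it moves along the equiangular direction of the active
set until either an inactive covariate's correlation with the residual ties
the active correlations (an entry event) or an active coefficient crosses
zero (a lasso drop event).  Mallows' Cp is tracked at every breakpoint and
the selected model is the first step attaining the minimum Cp.

Covariates must arrive standardized (mean 0, sd 1); the response is
centered internally, so coefficients live on the standardized-covariate
scale and the intercept is the response mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LarsStep", "LarsPath", "SelectedModel", "lars_fit", "mallows_cp", "select_min_cp"]

_TINY = 1e-12


@dataclass
class LarsStep:
    active: list[str]
    coef: np.ndarray  # full-length vector, zeros off the active set
    rss: float
    cp: float = np.nan


@dataclass
class LarsPath:
    steps: list[LarsStep]
    sigma2_hat: float
    column_names: list[str]
    y_mean: float
    n: int

    @property
    def selected_step(self) -> int:
        cps = [s.cp for s in self.steps]
        return int(np.argmin(cps))  # first minimum -> sparser model on ties

    def coefficients_at(self, step: int) -> pd.Series:
        return pd.Series(self.steps[step].coef, index=self.column_names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.steps):
            for j, name in enumerate(self.column_names):
                rows.append(
                    {"step": k, "covariate": name, "coefficient": s.coef[j],
                     "rss": s.rss, "cp": s.cp}
                )
        return pd.DataFrame(rows)


@dataclass
class SelectedModel:
    coefficients: pd.Series  # standardized scale; exact zeros off the active set
    intercept: float
    active_set: list[str] = field(default_factory=list)

    def predict(self, Z: pd.DataFrame | np.ndarray) -> np.ndarray:
        Z = np.asarray(pd.DataFrame(Z)[self.coefficients.index], dtype=float)
        return self.intercept + Z @ self.coefficients.to_numpy()


def _check_standardized(X: np.ndarray, names: list[str], tol: float = 1e-6) -> None:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = [n for n, m, s in zip(names, means, sds) if abs(m) > tol or abs(s - 1) > tol]
    if bad:
        raise ValueError(f"columns not standardized (mean 0, sd 1): {bad}")


def lars_fit(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_steps: int | None = None,
    check_standardized: bool = True,
) -> LarsPath:
    """Trace the full lasso path by least-angle regression.

    Returns a :class:`LarsPath` whose step 0 is the null model; each later
    step differs from its predecessor by exactly one covariate entering or
    (under the lasso modification) leaving the active set.  When n > p and
    the design has full rank, the final step is the OLS solution.
    """
    Xdf = pd.DataFrame(X)
    names = [str(c) for c in Xdf.columns]
    Xm = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    if check_standardized:
        _check_standardized(Xm, names)
    if max_steps is None:
        max_steps = min(n - 1, 8 * p)

    y_mean = float(y.mean())
    r = y - y_mean
    beta = np.zeros(p)
    active: list[int] = []
    blacklist: set[int] = set()
    max_active = min(p, n - 1)
    cor_tol = _TINY * max(1.0, float(np.abs(Xm.T @ r).max()))

    steps = [LarsStep(active=[], coef=beta.copy(), rss=float(r @ r))]
    just_dropped = False

    for _ in range(max_steps):
        c = Xm.T @ r
        C = float(np.abs(c).max()) if p else 0.0
        if C < cor_tol:
            break
        if not just_dropped:
            if len(active) >= max_active:
                break
            # admit the most correlated inactive covariate; skip entrants
            # that would make the active Gram matrix singular
            candidates = [j for j in np.argsort(-np.abs(c)) if j not in active and j not in blacklist]
            entered = False
            for j in candidates:
                trial = active + [int(j)]
                G = Xm[:, trial].T @ Xm[:, trial]
                if np.linalg.cond(G) > 1e10:
                    logger.warning("skipping rank-deficient entrant %s", names[j])
                    blacklist.add(int(j))
                    continue
                active = trial
                entered = True
                break
            if not entered:
                break
        just_dropped = False

        s = np.sign(c[active])
        XA = Xm[:, active] * s
        G = XA.T @ XA
        try:
            Ginv_one = np.linalg.solve(G, np.ones(len(active)))
        except np.linalg.LinAlgError:
            logger.warning("active Gram matrix became singular; stopping path early")
            break
        AA = 1.0 / np.sqrt(float(np.ones(len(active)) @ Ginv_one))
        w = AA * Ginv_one
        u = XA @ w  # unit equiangular vector
        a = Xm.T @ u

        inactive = [j for j in range(p) if j not in active]
        gamma_entry = C / AA
        if inactive:
            for j in inactive:
                for num, den in ((C - c[j], AA - a[j]), (C + c[j], AA + a[j])):
                    if den > _TINY:
                        g = num / den
                        if _TINY < g < gamma_entry:
                            gamma_entry = g

        d = s * w  # coefficient-space direction on the active set
        gamma_drop = np.inf
        drop_idx = -1
        for k, j in enumerate(active):
            if abs(d[k]) > _TINY:
                g = -beta[j] / d[k]
                if _TINY < g < gamma_drop:
                    gamma_drop = g
                    drop_idx = j

        gamma = min(gamma_entry, gamma_drop)
        for k, j in enumerate(active):
            beta[j] += gamma * d[k]
        r = r - gamma * u

        if gamma_drop < gamma_entry:  # lasso modification: coefficient hit zero
            beta[drop_idx] = 0.0
            active = [j for j in active if j != drop_idx]
            just_dropped = True

        steps.append(
            LarsStep(active=[names[j] for j in active], coef=beta.copy(), rss=float(r @ r))
        )

    sigma2_hat = _sigma2_full_ols(Xm, y - y_mean, fallback=steps[-1])
    path = LarsPath(steps=steps, sigma2_hat=sigma2_hat, column_names=names, y_mean=y_mean, n=n)
    mallows_cp(path)
    return path


def _sigma2_full_ols(Xc: np.ndarray, yc: np.ndarray, fallback: LarsStep) -> float:
    """Classical Cp error variance: RSS of the full OLS fit / (n - p - 1)."""
    n, p = Xc.shape
    if n > p + 1 and np.linalg.matrix_rank(Xc) == p:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        rss = float(np.sum((yc - Xc @ beta) ** 2))
        return rss / (n - p - 1)
    # saturated / rank-deficient designs: fall back to the last path step
    df = len(fallback.active) + 1
    return fallback.rss / max(n - df, 1)


def mallows_cp(path: LarsPath, sigma2_hat: float | None = None) -> np.ndarray:
    """Cp_k = RSS_k / sigma2 - n + 2 df_k with df_k = |active_k| + 1.

    A (near-)zero variance estimate arises only from an exactly-fitting
    full model; Cp then degenerates to 2 df_k - n for exact-fit steps and
    +inf otherwise, so selection returns the sparsest exact fit.
    """
    if sigma2_hat is None:
        sigma2_hat = path.sigma2_hat
    else:
        path.sigma2_hat = float(sigma2_hat)
    if sigma2_hat < 0:
        raise ValueError("sigma2_hat must be positive")
    n = path.n
    scale = max((s.rss for s in path.steps), default=1.0)
    cps = np.empty(len(path.steps))
    for k, s in enumerate(path.steps):
        df = len(s.active) + 1
        if sigma2_hat <= _TINY * max(scale, 1.0):
            cps[k] = 2.0 * df - n if s.rss <= _TINY * max(scale, 1.0) else np.inf
        else:
            cps[k] = s.rss / sigma2_hat - n + 2.0 * df
        s.cp = float(cps[k])
    return cps


def select_min_cp(path: LarsPath) -> SelectedModel:
    """Coefficients of the first path step attaining the minimum Cp.

    Ties break toward the earlier (sparser) step.
    """
    if not path.steps:
        raise ValueError("empty path")
    step = path.steps[path.selected_step]
    coefs = pd.Series(step.coef, index=path.column_names)
    return SelectedModel(
        coefficients=coefs,
        intercept=path.y_mean,
        active_set=[n for n in step.active],
    )
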