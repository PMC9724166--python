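"""Censoring-aware Pearson correlation between indicator pairs.

Non-detects sit somewhere below the detection limit / LLQ, so a single
substitution value would understate the uncertainty they carry.  Instead
the correlation is recomputed over repeated imputations: in each of
``n_reps`` (default 100) repetitions every censored entry is replaced by an
independent Uniform(0, limit) draw on the linear concentration scale, both
series are log-transformed, and a Pearson r is computed.  The average r is
reported together with its spread over repetitions, and significance comes
from the usual correlation t-test applied to the averaged r:
t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom, two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["CensoredCorrelation", "censored_pearson", "correlation_matrix"]

_SMALLEST_P = np.nextafter(0.0, 1.0)


def _log_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10_plus1":
        return np.log10(values + 1.0)
    if transform == "log10":
        return np.log10(values)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class CensoredCorrelation:
    mean_r: float
    sd_r: float
    p_value: float
    n_pairs: int
    n_reps: int
    seed: int
    p_underflowed: bool = False


def _t_test_p(r: float, n: int) -> tuple[float, bool]:
    if abs(r) >= 1.0:
        return _SMALLEST_P, True
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if p == 0.0:
        return _SMALLEST_P, True
    return p, False


def censored_pearson(
    x: np.ndarray,
    y: np.ndarray,
    x_censored: np.ndarray,
    y_censored: np.ndarray,
    x_limit: float,
    y_limit: float,
    x_transform: str = "log10",
    y_transform: str = "log10",
    n_reps: int = 100,
    seed: int = 0,
    impute_scale: str = "linear",
) -> CensoredCorrelation:
    """Average Pearson r over repeated below-limit imputations.

    ``impute_scale="linear"`` draws Uniform(0, limit) replacements in
    concentration units before the log transform (the default);
    ``"log"`` draws uniformly on the log10 scale between log10 of a small
    floor and log10(limit).  Rows where either series is missing (NaN) are
    excluded pairwise; at least 3 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = np.asarray(x_censored, dtype=bool)
    yc = np.asarray(y_censored, dtype=bool)
    if not (x.shape == y.shape == xc.shape == yc.shape):
        raise ValueError("x, y and censor flags must have equal length")
    if x_limit <= 0 or y_limit <= 0:
        raise ValueError("detection limits must be positive")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, xc, yc = x[keep], y[keep], xc[keep], yc[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")

    if not xc.any() and not yc.any():
        # imputation is inert: a single exact Pearson r, zero spread
        r = float(np.corrcoef(_log_transform(x, x_transform), _log_transform(y, y_transform))[0, 1])
        p, under = _t_test_p(r, n)
        if under:
            warnings.warn("|mean_r| at 1: p-value underflowed to the smallest positive float")
        return CensoredCorrelation(r, 0.0, p, n, n_reps, seed, under)

    rng = np.random.default_rng(seed)
    rs = np.empty(n_reps)
    for rep in range(n_reps):
        xi = x.copy()
        yi = y.copy()
        if impute_scale == "linear":
            xi[xc] = rng.uniform(0.0, x_limit, size=int(xc.sum()))
            yi[yc] = rng.uniform(0.0, y_limit, size=int(yc.sum()))
        elif impute_scale == "log":
            floor = 1e-6
            xi[xc] = 10 ** rng.uniform(np.log10(floor), np.log10(x_limit), size=int(xc.sum()))
            yi[yc] = 10 ** rng.uniform(np.log10(floor), np.log10(y_limit), size=int(yc.sum()))
        else:
            raise ValueError("impute_scale must be 'linear' or 'log'")
        rs[rep] = np.corrcoef(_log_transform(xi, x_transform), _log_transform(yi, y_transform))[0, 1]
    mean_r = float(rs.mean())
    sd_r = float(rs.std(ddof=0))
    p, under = _t_test_p(mean_r, n)
    if under:
        warnings.warn("|mean_r| at 1: p-value underflowed to the smallest positive float")
    return CensoredCorrelation(mean_r, sd_r, p, n, n_reps, seed, under)


def correlation_matrix(
    concentrations,
    censored,
    limits: dict[str, float],
    transforms: dict[str, str] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    impute_scale: str = "linear",
):
    """Pairwise censored correlations for a table of indicators.

    ``concentrations`` and ``censored`` are event x indicator DataFrames
    with matching columns.  Pairwise-complete observations are used per
    pair.  Returns (mean_r, sd_r, p) square DataFrames; the diagonal is
    r = 1 with p = 0.
    """
    import pandas as pd

    conc = pd.DataFrame(concentrations)
    cens = pd.DataFrame(censored)
    names = list(conc.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 indicators")
    if list(cens.columns) != names:
        raise ValueError("concentration and censor tables must share columns")
    transforms = transforms or {}
    for name in names:
        col_cens = cens[name][conc[name].notna()]
        if len(col_cens) and col_cens.all():
            warnings.warn(f"indicator {name!r} is entirely censored; all values imputed")

    mean_r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    sd_r = pd.DataFrame(0.0, index=names, columns=names)
    p = pd.DataFrame(0.0, index=names, columns=names)
    # one independent child seed per pair, stable in pair order
    children = np.random.SeedSequence(seed).spawn(len(names) * (len(names) - 1) // 2)
    for (a, b), ss in zip(combinations(names, 2), children):
        res = censored_pearson(
            conc[a].to_numpy(float),
            conc[b].to_numpy(float),
            cens[a].to_numpy(bool),
            cens[b].to_numpy(bool),
            limits[a],
            limits[b],
            x_transform=transforms.get(a, "log10"),
            y_transform=transforms.get(b, "log10"),
            n_reps=n_reps,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            impute_scale=impute_scale,
        )
        mean_r.loc[a, b] = mean_r.loc[b, a] = res.mean_r
        sd_r.loc[a, b] = sd_r.loc[b, a] = res.sd_r
        p.loc[a, b] = p.loc[b, a] = res.p_value
    return mean_r, sd_r, p
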