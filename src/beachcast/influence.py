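"""Covariate influence across site/indicator models.

One minimum-Cp LARS-lasso model is fitted per site and indicator on all
available data; only its coefficients are used here.  Influence of a
covariate across the model set is scored by three metrics: (1) the sum of
absolute regression coefficients, (2) the proportion of models in which
its coefficient is non-zero, and (3) the Total Score, the sum of the two.
Related covariates can be aggregated before scoring (cumulative rainfall
lags into "rainfall"; the two wind components into "wind"), where a group's
magnitude per model is the sum of member magnitudes and the group occurs in
a model if any member does.

The coefficient table convention throughout: one row per model, one column
per covariate, signed coefficients; NaN marks a covariate not measured at
that model's site (distinct from an exact zero), and such models drop out
of that covariate's occurrence denominator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from beachcast.lars import lars_fit, select_min_cp
from beachcast.preprocess import ModelFrame

__all__ = [
    "full_data_coefficients",
    "coefficient_table",
    "aggregate_covariates",
    "influence_scores",
    "heatmap_matrix",
    "write_heatmap_csv",
    "read_heatmap_csv",
]

NA_SENTINEL = "NA"


def full_data_coefficients(frame: ModelFrame) -> pd.Series:
    """Minimum-Cp coefficients from a fit on the complete dataset (no CV)."""
    path = lars_fit(frame.X, frame.y)
    return select_min_cp(path).coefficients


def coefficient_table(models: Mapping[tuple[str, str], pd.Series]) -> pd.DataFrame:
    """Stack per-model coefficient vectors into the models x covariates table.

    Keys are (site, indicator).  Covariates absent from a model's vector
    become NaN (not available at that site).
    """
    table = pd.DataFrame(
        {key: coefs for key, coefs in models.items()}
    ).T.sort_index(axis=1)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["site", "indicator"])
    return table


def aggregate_covariates(
    coef_table: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Replace grouped columns by per-model group influence magnitudes.

    A group's value in a model is the sum of its members' absolute
    coefficients — non-zero iff any member is non-zero — and NaN only when
    every member is unavailable there.  Ungrouped covariates pass through
    unchanged (their signed values kept).
    """
    out = coef_table.copy()
    for group, members in groups.items():
        missing = [m for m in members if m not in coef_table.columns]
        if missing:
            raise KeyError(f"group {group!r}: unknown member(s) {missing}")
        block = coef_table[list(members)].abs()
        agg = block.sum(axis=1, min_count=1)  # NaN iff all members NaN
        out = out.drop(columns=list(members))
        out[group] = agg
    return out.sort_index(axis=1)


def influence_scores(
    coef_table: pd.DataFrame, groups: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Summed |coefficients|, occurrence proportion and Total Score.

    ``n_models`` counts the models where the covariate was available; the
    occurrence proportion uses that count as its denominator, so covariates
    measured at a single site are scored over that site's models only.
    Rows are sorted by Total Score, descending.
    """
    if len(coef_table) < 1:
        raise ValueError("need at least one model")
    table = aggregate_covariates(coef_table, groups) if groups else coef_table
    available = table.notna()
    n_models = available.sum(axis=0)
    summed = table.abs().sum(axis=0, min_count=1).fillna(0.0)
    nonzero = ((table != 0) & available).sum(axis=0)
    proportion = (nonzero / n_models.replace(0, np.nan)).fillna(0.0)
    out = pd.DataFrame(
        {
            "summed_coefficients": summed,
            "proportion_occurrence": proportion,
            "total_score": summed + proportion,
            "n_models": n_models.astype(int),
        }
    )
    out.index.name = "covariate"
    return out.sort_values("total_score", ascending=False)


def heatmap_matrix(site_models: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Covariate x indicator matrix of signed coefficients for one site.

    Covariates are ordered alphabetically; NaN cells mark covariates with
    no data at the site (never conflated with an exact zero).
    """
    mat = pd.DataFrame({ind: coefs for ind, coefs in site_models.items()})
    mat = mat.sort_index(axis=0)
    mat.index.name = "covariate"
    return mat


def write_heatmap_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, na_rep=NA_SENTINEL)


def read_heatmap_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=[NA_SENTINEL])
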