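"""Raw beach-season table -> modeling frame.

Responses are log10-transformed (log10(C+1) for coliphage, whose
concentrations can fall below 1 PFU/L), non-detects are substituted at half
the detection limit / lower limit of quantification before transforming,
wind speed and direction are decomposed into alongshore and onshore
components relative to the beach orientation, covariates are standardized,
and highly collinear covariate pairs (|r| >= 0.8 by default) are thinned to
one member each.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeachSeason",
    "ModelFrame",
    "transform_response",
    "decompose_wind",
    "standardize",
    "collinearity_filter",
    "describe_indicators",
    "build_model_frame",
]

TRANSFORMS = ("log10", "log10_plus1")


@dataclass
class BeachSeason:
    """One site-season of sampling events.

    ``events`` holds one row per sampling event with covariate columns plus
    per-indicator pairs ``<name>_conc`` (linear units) and
    ``<name>_censored`` (below detection limit / LLQ).  ``limits`` maps
    indicator name to its detection limit or LLQ in linear units and
    ``transforms`` to the log transform used for that indicator family.
    """

    site: str
    events: pd.DataFrame
    limits: dict[str, float]
    transforms: dict[str, str] = field(default_factory=dict)
    beach_orientation: float = 0.0

    @property
    def indicators(self) -> list[str]:
        return [c[: -len("_conc")] for c in self.events.columns if c.endswith("_conc")]

    @property
    def covariates(self) -> list[str]:
        skip = {"site", "date"}
        return [
            c
            for c in self.events.columns
            if c not in skip and not c.endswith("_conc") and not c.endswith("_censored")
        ]

    def transform_for(self, indicator: str) -> str:
        return self.transforms.get(indicator, "log10")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        limits: Mapping[str, float],
        transforms: Mapping[str, str] | None = None,
        beach_orientation: float = 0.0,
    ) -> "BeachSeason":
        events = pd.read_csv(path)
        site = str(events["site"].iloc[0]) if "site" in events.columns else ""
        return cls(
            site=site,
            events=events,
            limits=dict(limits),
            transforms=dict(transforms or {}),
            beach_orientation=beach_orientation,
        )


@dataclass
class ModelFrame:
    """Standardized covariate matrix + log10 response for one model."""

    X: pd.DataFrame
    y: np.ndarray
    standardization_params: pd.DataFrame  # index = column, columns = mean, sd
    dropped_covariates: list[tuple[str, str]] = field(default_factory=list)
    site: str = ""
    indicator: str = ""

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    def raw_X(self) -> pd.DataFrame:
        """Invert the standardization exactly (for per-fold refits)."""
        p = self.standardization_params
        return self.X * p["sd"] + p["mean"]

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out.insert(0, "y", self.y)
        out.to_csv(path, index=False)
        sidecar = {
            "site": self.site,
            "indicator": self.indicator,
            "standardization": {
                c: {"mean": float(r["mean"]), "sd": float(r["sd"])}
                for c, r in self.standardization_params.iterrows()
            },
            "dropped_covariates": [list(t) for t in self.dropped_covariates],
        }
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModelFrame":
        df = pd.read_csv(path)
        y = df.pop("y").to_numpy(float)
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        params = pd.DataFrame(meta["standardization"]).T[["mean", "sd"]]
        return cls(
            X=df,
            y=y,
            standardization_params=params,
            dropped_covariates=[tuple(t) for t in meta.get("dropped_covariates", [])],
            site=meta.get("site", ""),
            indicator=meta.get("indicator", ""),
        )


def transform_response(
    concentrations: np.ndarray,
    censored: np.ndarray,
    limit: float,
    transform: str = "log10",
    substitute_fraction: float = 0.5,
) -> np.ndarray:
    """log10 response with below-limit substitution.

    Censored entries are replaced by ``substitute_fraction * limit`` (half
    the detection limit / LLQ by default) on the linear scale before the
    transform; uncensored entries are transformed directly.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    if limit <= 0:
        raise ValueError("detection limit / LLQ must be positive")
    conc = np.asarray(concentrations, dtype=float).copy()
    cens = np.asarray(censored, dtype=bool)
    if conc.shape != cens.shape:
        raise ValueError("concentrations and censored flags must have equal length")
    conc[cens] = substitute_fraction * limit
    if transform == "log10":
        if np.any(conc <= 0):
            raise ValueError(
                "zero or negative concentration under plain log10 without a censor flag"
            )
        return np.log10(conc)
    return np.log10(conc + 1.0)


def decompose_wind(
    speed: np.ndarray,
    direction_deg: np.ndarray,
    beach_orientation_deg: float,
    direction_convention: str = "from",
) -> tuple[np.ndarray, np.ndarray]:
    """Split wind into alongshore (Wind-A) and onshore/offshore (Wind-O).

    ``beach_orientation_deg`` is the azimuth of the shore-normal pointing
    from water to land.  Meteorological directions report where the wind
    blows *from*; they are flipped to "toward" before projecting
    (``direction_convention="toward"`` skips the flip).  Positive Wind-O
    blows onshore; Wind-A is the component parallel to the shoreline.
    The components satisfy wind_A**2 + wind_O**2 == speed**2.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("wind speed must be non-negative")
    direction = np.asarray(direction_deg, dtype=float)
    if direction_convention == "from":
        direction = direction + 180.0
    elif direction_convention != "toward":
        raise ValueError("direction_convention must be 'from' or 'toward'")
    theta = np.deg2rad(direction - beach_orientation_deg)
    wind_o = speed * np.cos(theta)
    wind_a = speed * np.sin(theta)
    return wind_a, wind_o


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale each column to mean 0, sd 1 (sample sd, ddof=1).

    Returns the standardized frame and a params frame (mean, sd per column)
    that supports an exact inverse transform and application to new data.
    """
    X = pd.DataFrame(X)
    means = X.mean()
    sds = X.std(ddof=1)
    zero = sds[~(sds > 0)].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    Z = (X - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds})
    return Z, params


def apply_standardization(X: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return (pd.DataFrame(X)[params.index] - params["mean"]) / params["sd"]


def collinearity_filter(
    X: pd.DataFrame,
    threshold: float = 0.8,
    pairs_to_check: Sequence[tuple[str, str]] | None = None,
    exclude: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every covariate pair with |r| >= threshold.

    ``exclude`` names covariates preferred for dropping (the study excluded
    UV254 and 48 h rainfall); for pairs not covered by the exclusion list the
    member with the larger mean absolute correlation to all other covariates
    is dropped.  Returns (retained column names, report of
    (covariate_a, covariate_b, r, dropped)).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    X = pd.DataFrame(X)
    corr = X.corr()
    exclude = set(exclude or ())
    cols = list(X.columns)
    if pairs_to_check is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    else:
        pairs = [tuple(p) for p in pairs_to_check]
    flagged = [(a, b, corr.loc[a, b]) for a, b in pairs if abs(corr.loc[a, b]) >= threshold]
    flagged.sort(key=lambda t: -abs(t[2]))
    mean_abs = corr.abs().sum() - 1.0  # total |r| to the other covariates
    dropped: set[str] = set()
    report_rows = []
    for a, b, r in flagged:
        if a in dropped or b in dropped:
            continue  # pair already resolved by an earlier, stronger pair
        if a in exclude:
            victim = a
        elif b in exclude:
            victim = b
        else:
            victim = a if mean_abs[a] >= mean_abs[b] else b
        dropped.add(victim)
        report_rows.append({"covariate_a": a, "covariate_b": b, "r": r, "dropped": victim})
    retained = [c for c in cols if c not in dropped]
    report = pd.DataFrame(report_rows, columns=["covariate_a", "covariate_b", "r", "dropped"])
    return retained, report


def describe_indicators(season: BeachSeason, substitute_fraction: float = 0.5) -> pd.DataFrame:
    """Summary statistics of per-indicator log10 concentrations.

    Non-detects are substituted at half the limit before transforming, so
    n counts every event with a measurement.  CV = sd / mean of the log10
    values.  An all-censored indicator is flagged (statistics then rest
    entirely on substituted values).
    """
    rows = []
    for ind in season.indicators:
        conc = season.events[f"{ind}_conc"].to_numpy(float)
        cens = season.events[f"{ind}_censored"].to_numpy(bool)
        ok = ~np.isnan(conc)
        conc, cens = conc[ok], cens[ok]
        if conc.size < 2:  # substituted values count as usable
            raise ValueError(f"indicator {ind!r}: need at least 2 usable values")
        logv = transform_response(
            conc, cens, season.limits[ind], season.transform_for(ind), substitute_fraction
        )
        mean = float(np.mean(logv))
        sd = float(np.std(logv, ddof=1))
        rows.append(
            {
                "indicator": ind,
                "n": int(conc.size),
                "n_censored": int(cens.sum()),
                "min": float(np.min(logv)),
                "max": float(np.max(logv)),
                "mean": mean,
                "sd": sd,
                "cv": sd / mean if mean != 0 else np.inf,
                "all_censored": bool(cens.all()),
            }
        )
        if cens.all():
            warnings.warn(f"indicator {ind!r}: all values censored; statistics are substitutions")
    return pd.DataFrame(rows).set_index("indicator")


def build_model_frame(
    season: BeachSeason,
    indicator: str,
    covariates: Sequence[str] | None = None,
    collinearity_threshold: float = 0.8,
    exclude: Sequence[str] | None = None,
    substitute_fraction: float = 0.5,
    decompose_wind_columns: tuple[str, str] | None = ("wind_speed", "wind_direction"),
) -> ModelFrame:
    """Assemble the standardized modeling frame for one indicator.

    Steps: optional wind decomposition, row-wise deletion of events with a
    missing covariate or response, response transform with half-limit
    substitution, collinearity filtering, standardization.
    """
    if indicator not in season.indicators:
        raise KeyError(f"unknown indicator {indicator!r}")
    events = season.events.copy()
    if decompose_wind_columns is not None:
        sp_col, dir_col = decompose_wind_columns
        if sp_col in events.columns and dir_col in events.columns:
            wind_a, wind_o = decompose_wind(
                events[sp_col].to_numpy(float),
                events[dir_col].to_numpy(float),
                season.beach_orientation,
            )
            events["wind_a"] = wind_a
            events["wind_o"] = wind_o
            events = events.drop(columns=[sp_col, dir_col])
    if covariates is None:
        skip = {"site", "date"}
        covariates = [
            c
            for c in events.columns
            if c not in skip and not c.endswith("_conc") and not c.endswith("_censored")
        ]
    sub = events[list(covariates) + [f"{indicator}_conc", f"{indicator}_censored"]].dropna()
    y = transform_response(
        sub[f"{indicator}_conc"].to_numpy(float),
        sub[f"{indicator}_censored"].to_numpy(bool),
        season.limits[indicator],
        season.transform_for(indicator),
        substitute_fraction,
    )
    Xraw = sub[list(covariates)]
    retained, report = collinearity_filter(Xraw, collinearity_threshold, exclude=exclude)
    dropped = [(r["dropped"], f"|r|={abs(r['r']):.3f} with "
                f"{r['covariate_a'] if r['dropped'] != r['covariate_a'] else r['covariate_b']}")
               for _, r in report.iterrows()]
    Z, params = standardize(Xraw[retained])
    return ModelFrame(
        X=Z,
        y=y,
        standardization_params=params,
        dropped_covariates=dropped,
        site=season.site,
        indicator=indicator,
    )
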