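"""Synthetic beach-season and qPCR-run generators.

The season generator emulates the statistical structure the downstream
analysis assumes: a suite of environmental covariates with realistic
marginals and configured collinear pairs (a Gaussian copula couples
non-Gaussian marginals while approximately preserving the target Pearson
correlations), a sparse linear signal on standardized covariates producing
a log10-scale microbial response with Gaussian noise, and left-censoring of
the back-transformed concentration at a detection limit / LLQ.

The qPCR generator lays out a plate the way the quantification workbooks
expect it: dilution-series standards across instrument runs, whole-cell
calibrators, negative (filter blank) controls and duplicated test samples,
each with target, IAC and Sketa22 channels; named quality-control gate
violations can be injected deliberately so the gate logic is testable.

Randomness: every generator derives independent child streams from its
config's single ``seed`` via ``numpy.random.SeedSequence([seed, k])`` — a
documented splitting scheme, so covariates, response noise and qPCR noise
can be re-drawn independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from beachcast.qpcr import QPCRRun

__all__ = [
    "CovariateSpec",
    "SeasonSimConfig",
    "SimulatedSeason",
    "QPCRSimConfig",
    "simulate_covariates",
    "simulate_indicators",
    "simulate_qpcr_run",
    "simulate_season",
    "DEFAULT_COVARIATES",
    "DEFAULT_CORRELATIONS",
    "DEFAULT_INDICATOR_TRUTHS",
]

FAMILIES = ("gaussian", "lognormal", "negative-binomial-count", "circular-direction")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal for one covariate.

    Interpretation of (mean, dispersion) by family: gaussian — mean and sd;
    lognormal — mean and sd of the natural log; negative-binomial-count —
    mean count and size (inverse overdispersion); circular-direction —
    mean direction and angular sd in degrees (wrapped normal).
    """

    name: str
    family: str
    mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"{self.name}: unknown marginal family {self.family!r}")
        if self.dispersion < 0:
            raise ValueError(f"{self.name}: dispersion must be non-negative")


# Default covariate suite: the routinely collected water and beach-site
# parameters of Great Lakes monitoring programs, with magnitudes typical of
# a mid-summer lake beach.
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("water_temp", "gaussian", 21.0, 3.0),        # deg C
    CovariateSpec("turbidity", "lognormal", 2.0, 0.7),          # NTU
    CovariateSpec("dissolved_oxygen", "gaussian", 8.5, 1.2),    # mg/L
    CovariateSpec("conductivity", "gaussian", 300.0, 40.0),     # umhos/cm
    CovariateSpec("ph", "gaussian", 8.2, 0.25),
    CovariateSpec("doc", "lognormal", 1.5, 0.3),                # mg C/L
    CovariateSpec("uv254", "lognormal", -2.3, 0.35),            # 1/m
    CovariateSpec("wind_speed", "lognormal", 2.2, 0.5),         # km/h
    CovariateSpec("wind_direction", "circular-direction", 225.0, 80.0),  # deg
    CovariateSpec("air_temp", "gaussian", 23.0, 4.0),           # deg C
    CovariateSpec("wave_height", "lognormal", -1.4, 0.6),       # m
    CovariateSpec("rel_humidity", "gaussian", 70.0, 10.0),      # percent
    CovariateSpec("rain_24h", "lognormal", 0.0, 1.2),           # mm
    CovariateSpec("rain_48h", "lognormal", 0.6, 1.2),           # mm
    CovariateSpec("rain_72h", "lognormal", 1.0, 1.2),           # mm
    CovariateSpec("par", "lognormal", 6.0, 0.5),                # mol/m2-s
    CovariateSpec("humans", "negative-binomial-count", 25.0, 4.0),
    CovariateSpec("birds", "negative-binomial-count", 30.0, 2.5),
    CovariateSpec("dogs", "negative-binomial-count", 2.0, 1.5),
)

# Collinear pairs observed in routine covariate suites; the third rainfall
# pair is implied by the two stated lag correlations (needed for a positive
# semi-definite target matrix).
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("uv254", "doc", 0.81),
    ("rain_24h", "rain_48h", 0.84),
    ("rain_48h", "rain_72h", 0.89),
    ("rain_24h", "rain_72h", 0.75),
)


@dataclass
class SeasonSimConfig:
    n_events: int = 65
    covariate_spec: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    target_correlations: tuple[tuple[str, str, float], ...] = DEFAULT_CORRELATIONS
    true_coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 2.0
    noise_sd: float = 0.45
    censor_limit: float = 1.0
    response_transform: str = "log10"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 10:
            raise ValueError("n_events must be at least 10")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.censor_limit < 0:
            raise ValueError("censor_limit must be non-negative")
        if self.response_transform not in ("log10", "log10_plus1"):
            raise ValueError("response_transform must be 'log10' or 'log10_plus1'")


@dataclass
class SimulatedSeason:
    covariates: pd.DataFrame
    true_log10_response: np.ndarray
    observed_concentration: np.ndarray
    censored: np.ndarray
    truth: dict


def _latent_rho(spec_a: CovariateSpec, spec_b: CovariateSpec, r: float) -> float:
    """Latent-normal correlation that yields Pearson r after the marginals.

    Closed forms exist for gaussian/lognormal pairs (the lognormal transform
    attenuates correlation, so the latent rho is inflated to compensate);
    other marginal combinations use rho = r, which is approximate.
    """
    fams = (spec_a.family, spec_b.family)
    if fams == ("gaussian", "gaussian"):
        return r
    if fams == ("lognormal", "lognormal"):
        sa, sb = spec_a.dispersion, spec_b.dispersion
        arg = 1.0 + r * np.sqrt(np.expm1(sa * sa) * np.expm1(sb * sb))
        if arg <= 0:
            raise ValueError(
                f"target r({spec_a.name}, {spec_b.name}) = {r} unattainable "
                "under these lognormal marginals"
            )
        rho = np.log(arg) / (sa * sb)
    elif "lognormal" in fams and "gaussian" in fams:
        s = spec_a.dispersion if spec_a.family == "lognormal" else spec_b.dispersion
        rho = r * np.sqrt(np.expm1(s * s)) / s
    else:
        return r
    if abs(rho) > 1:
        raise ValueError(
            f"target r({spec_a.name}, {spec_b.name}) = {r} unattainable: "
            f"implied latent correlation {rho:.3f} exceeds 1"
        )
    return float(rho)


def _correlation_matrix(config: SeasonSimConfig) -> np.ndarray:
    names = [s.name for s in config.covariate_spec]
    specs = {s.name: s for s in config.covariate_spec}
    idx = {n: i for i, n in enumerate(names)}
    R = np.eye(len(names))
    for a, b, r in config.target_correlations:
        for n in (a, b):
            if n not in idx:
                raise KeyError(f"target correlation references unknown covariate {n!r}")
        if abs(r) > 1:
            raise ValueError(f"target correlation r({a}, {b}) = {r} outside [-1, 1]")
        if abs(r) >= 1.0 - 1e-12 and specs[a] != specs[b]:
            raise ValueError(
                f"degenerate target r({a}, {b}) = {r} with conflicting marginals"
            )
        rho = _latent_rho(specs[a], specs[b], r)
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-8:
        pairs = ", ".join(f"({a}, {b}, r={r})" for a, b, r in config.target_correlations)
        raise ValueError(
            f"target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g}); check the configured pairs: {pairs}"
        )
    return R


def simulate_covariates(config: SeasonSimConfig) -> pd.DataFrame:
    """Draw the event x covariate table via a Gaussian copula.

    A multivariate normal with the target correlation matrix is transformed
    column-wise to each covariate's marginal; monotone transforms keep the
    configured Pearson correlations approximately (exactly for jointly
    Gaussian columns).  Counts come out as non-negative integers and
    directions in [0, 360).
    """
    R = _correlation_matrix(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    eigval, eigvec = np.linalg.eigh(R)
    L = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    Z = rng.standard_normal((config.n_events, len(config.covariate_spec))) @ L.T
    cols = {}
    for j, spec in enumerate(config.covariate_spec):
        z = Z[:, j]
        if spec.family == "gaussian":
            cols[spec.name] = spec.mean + spec.dispersion * z
        elif spec.family == "lognormal":
            cols[spec.name] = np.exp(spec.mean + spec.dispersion * z)
        elif spec.family == "negative-binomial-count":
            u = stats.norm.cdf(z)
            k, m = spec.dispersion, spec.mean
            cols[spec.name] = stats.nbinom.ppf(u, n=k, p=k / (k + m)).astype(int)
        else:  # circular-direction: wrapped normal
            cols[spec.name] = np.mod(spec.mean + spec.dispersion * z, 360.0)
    return pd.DataFrame(cols)


def simulate_indicators(covariates: pd.DataFrame, config: SeasonSimConfig) -> SimulatedSeason:
    """Sparse linear log10 signal + Gaussian noise, then left-censoring.

    true response = intercept + sum coef_j * z(covariate_j) + N(0, noise_sd)
    on standardized covariates; the observed concentration is the
    back-transform (10**y, or 10**y - 1 under log10_plus1, floored at 0)
    and the censoring flag marks concentrations below ``censor_limit`` —
    censoring acts on the noisy measurement, after the noise.
    """
    unknown = [k for k in config.true_coefficients if k not in covariates.columns]
    if unknown:
        raise KeyError(f"true_coefficients name unknown covariate(s): {unknown}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lin = np.full(len(covariates), float(config.intercept))
    for name, coef in config.true_coefficients.items():
        col = covariates[name].to_numpy(float)
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        lin += coef * (col - col.mean()) / sd
    response = lin + rng.normal(0.0, config.noise_sd, size=len(covariates))
    if config.response_transform == "log10":
        conc = 10.0 ** response
    else:
        conc = np.maximum(10.0 ** response - 1.0, 0.0)
    censored = conc < config.censor_limit
    truth = {
        "coefficients": dict(config.true_coefficients),
        "intercept": config.intercept,
        "noise_sd": config.noise_sd,
        "censor_limit": config.censor_limit,
        "response_transform": config.response_transform,
    }
    return SimulatedSeason(
        covariates=covariates,
        true_log10_response=response,
        observed_concentration=conc,
        censored=censored,
        truth=truth,
    )


# Per-indicator generative truths for the default seven-indicator season:
# (coefficients on standardized covariates, intercept in log10 units, noise
# sd in log10 units, linear censor limit, response transform).  Rainfall,
# bird abundance and wave height carry most of the signal; the F+ coliphage
# and E. coli qPCR indicators are given weak signal and (for F+) frequent
# censoring, the regimes where forecasting is known to struggle.
DEFAULT_INDICATOR_TRUTHS: dict[str, dict] = {
    "fplus_coliphage": dict(
        coefficients={"rain_24h": 0.10, "turbidity": 0.08},
        intercept=0.70, noise_sd=0.50, censor_limit=1.6, transform="log10_plus1",
    ),
    "somatic_coliphage": dict(
        coefficients={"rain_24h": 0.25, "birds": 0.15, "wave_height": 0.20},
        intercept=2.30, noise_sd=0.45, censor_limit=1.6, transform="log10_plus1",
    ),
    "ecoli_culture": dict(
        coefficients={"rain_24h": 0.25, "turbidity": 0.20, "wave_height": 0.15},
        intercept=2.20, noise_sd=0.40, censor_limit=1.0, transform="log10",
    ),
    "entero_culture": dict(
        coefficients={"rain_24h": 0.28, "birds": 0.18, "wave_height": 0.15},
        intercept=1.90, noise_sd=0.45, censor_limit=1.0, transform="log10",
    ),
    "ecoli_qpcr": dict(
        coefficients={"rain_24h": 0.12, "doc": 0.10},
        intercept=3.80, noise_sd=0.50, censor_limit=679.0, transform="log10",
    ),
    "entero_qpcr": dict(
        coefficients={"rain_24h": 0.30, "birds": 0.20, "wave_height": 0.18},
        intercept=2.30, noise_sd=0.40, censor_limit=48.0, transform="log10",
    ),
    "bac_qpcr": dict(
        coefficients={"rain_24h": 0.20, "doc": 0.15, "turbidity": 0.10},
        intercept=4.80, noise_sd=0.45, censor_limit=724.0, transform="log10",
    ),
}


def simulate_season(
    seed: int = 0,
    n_events: int = 65,
    site: str = "synthetic_beach",
    indicator_truths: dict[str, dict] | None = None,
    covariate_spec: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES,
    target_correlations: tuple[tuple[str, str, float], ...] = DEFAULT_CORRELATIONS,
) -> tuple[pd.DataFrame, dict]:
    """One full site-season: shared covariates + seven censored indicators.

    Returns the canonical season table (site, date, covariate columns,
    then per-indicator ``<name>_conc`` / ``<name>_censored`` pairs) and the
    ground-truth dict (per-indicator coefficients, intercepts, noise and
    limits) for parameter-recovery checks.
    """
    truths = indicator_truths or DEFAULT_INDICATOR_TRUTHS
    base = SeasonSimConfig(
        n_events=n_events,
        covariate_spec=covariate_spec,
        target_correlations=target_correlations,
        seed=seed,
    )
    covariates = simulate_covariates(base)
    table = covariates.copy()
    table.insert(0, "date", pd.date_range("2022-06-01", periods=n_events, freq="D").strftime("%Y-%m-%d"))
    table.insert(0, "site", site)
    truth_out: dict = {"seed": seed, "site": site, "indicators": {}}
    for k, (name, t) in enumerate(truths.items()):
        cfg = replace(
            base,
            true_coefficients=t["coefficients"],
            intercept=t["intercept"],
            noise_sd=t["noise_sd"],
            censor_limit=t["censor_limit"],
            response_transform=t["transform"],
            seed=int(np.random.SeedSequence([seed, 2, k]).generate_state(1)[0] % (2**31)),
        )
        sim = simulate_indicators(covariates, cfg)
        table[f"{name}_conc"] = sim.observed_concentration
        table[f"{name}_censored"] = sim.censored
        truth_out["indicators"][name] = dict(sim.truth)
    return table, truth_out


@dataclass
class QPCRSimConfig:
    true_slope: float = -3.49  # Ct per log10 copies
    true_intercept: float = 37.93  # Ct at 1 copy/reaction
    standards_log10_copies: tuple[float, ...] = tuple(np.log10(6.0) + k for k in range(6))
    replicates_per_level: int = 3
    ct_noise_sd: float = 0.1
    n_standard_runs: int = 2
    n_calibrators: int = 3
    n_negatives: int = 3
    n_test_samples: int = 4
    calibrator_log10_copies: float = 4.0
    test_log10_copies: float = 3.0
    sketa_mean_ct: float = 24.0
    iac_mean_ct: float = 30.0
    inject_failures: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_slope >= 0:
            raise ValueError("true_slope must be negative")
        span = max(self.standards_log10_copies) - min(self.standards_log10_copies)
        if span < 3:
            raise ValueError("standards must span at least 3 log10 levels")
        known = {"ancova", "calibrator_window", "sketa_window", "iac_window",
                 "negative_llq", "duplicate_ct_spread"}
        bad = set(self.inject_failures) - known
        if bad:
            raise ValueError(f"unknown gate name(s) in inject_failures: {sorted(bad)}")


def simulate_qpcr_run(config: QPCRSimConfig) -> QPCRRun:
    """Lay out a synthetic plate; optionally violate named QC gates.

    Standards follow Ct = intercept + slope * log10(copies) + noise across
    ``n_standard_runs`` instrument runs; negatives' target channel is
    undetected; calibrators and duplicated test samples carry target,
    Sketa22 and IAC channels.  Each name in ``inject_failures`` perturbs
    the run so that exactly that quality gate trips.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    inject = set(config.inject_failures)
    sd_ref = max(config.ct_noise_sd, 0.1)

    def noise() -> float:
        return float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd > 0 else 0.0

    def line(l10: float, slope: float) -> float:
        return config.true_intercept + slope * l10

    rows: list[dict] = []
    well = 0

    def add(run_id: str, role: str, assay: str, sample_id: str,
            l10: float | None, ct: float | None) -> None:
        nonlocal well
        well += 1
        rows.append(
            {"well": f"W{well:03d}", "run_id": run_id, "role": role, "assay": assay,
             "sample_id": sample_id, "log10_copies": np.nan if l10 is None else l10,
             "ct": np.nan if ct is None else ct}
        )

    for r in range(config.n_standard_runs):
        slope = config.true_slope
        if "ancova" in inject and r == config.n_standard_runs - 1:
            slope = config.true_slope + 0.6  # tilt the last run's curve
        for l10 in config.standards_log10_copies:
            for _ in range(config.replicates_per_level):
                add(f"run{r + 1}", "standard", "target", f"std_{l10:.3f}", l10,
                    line(l10, slope) + noise())

    cal_target_nominal = line(config.calibrator_log10_copies, config.true_slope)
    cal_shift = 3.0 * sd_ref + 1.0 if "calibrator_window" in inject else 0.0
    for i in range(config.n_calibrators):
        sid = f"cal{i + 1}"
        add("run1", "calibrator", "target", sid, None, cal_target_nominal + cal_shift + noise())
        add("run1", "calibrator", "Sketa22", sid, None, config.sketa_mean_ct + noise())
        add("run1", "calibrator", "IAC", sid, None, config.iac_mean_ct + noise())

    for i in range(config.n_negatives):
        sid = f"neg{i + 1}"
        if "negative_llq" in inject:
            add("run1", "negative", "target", sid, None, cal_target_nominal + noise())
        else:
            add("run1", "negative", "target", sid, None, None)  # undetected
        add("run1", "negative", "Sketa22", sid, None, config.sketa_mean_ct + noise())
        add("run1", "negative", "IAC", sid, None, config.iac_mean_ct + noise())

    test_ct = line(config.test_log10_copies, config.true_slope)
    sketa_shift = 4.0 if "sketa_window" in inject else 0.0
    iac_shift = 2.0 if "iac_window" in inject else 0.0
    for i in range(config.n_test_samples):
        sid = f"test{i + 1}"
        for dup in range(2):
            dup_shift = 5.0 if ("duplicate_ct_spread" in inject and dup == 1) else 0.0
            add("run1", "test", "target", sid, None, test_ct + dup_shift + noise())
            add("run1", "test", "Sketa22", sid, None, config.sketa_mean_ct + sketa_shift + noise())
            add("run1", "test", "IAC", sid, None, config.iac_mean_ct + iac_shift + noise())

    thresholds = {
        "cal_target_mean": cal_target_nominal,
        "cal_target_sd": sd_ref,
        "cal_sketa_mean": config.sketa_mean_ct,
        "cal_sketa_sd": sd_ref,
    }
    return QPCRRun(wells=pd.DataFrame(rows), gate_thresholds=thresholds)
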