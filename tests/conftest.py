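import numpy as np
import pandas as pd
import pytest

from beachcast.preprocess import BeachSeason, ModelFrame, standardize


def standardized_design(seed: int, n: int, p: int) -> np.ndarray:
    """Random design with columns centered and scaled to sd 1 (ddof=1)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def orthonormal_design(seed: int, n: int, p: int) -> np.ndarray:
    """Standardized design whose columns are also mutually orthogonal.

    Columns are orthonormalized in the space orthogonal to the intercept,
    then rescaled so each has sample sd 1; hence X.T @ X = (n - 1) * I.
    """
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, p))
    M = M - M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q * np.sqrt(n - 1)


@pytest.fixture
def small_season() -> BeachSeason:
    """Tiny two-indicator season with a known censored mix."""
    rng = np.random.default_rng(42)
    n = 24
    events = pd.DataFrame(
        {
            "site": "testbeach",
            "date": pd.date_range("2022-07-01", periods=n).strftime("%Y-%m-%d"),
            "turbidity": rng.lognormal(2.0, 0.5, n),
            "rain_24h": rng.lognormal(0.0, 1.0, n),
            "birds": rng.poisson(20, n),
        }
    )
    conc = rng.lognormal(np.log(200), 1.0, n)
    events["entero_conc"] = conc
    events["entero_censored"] = conc < 50.0
    phage = rng.lognormal(np.log(3), 1.0, n)
    events["phage_conc"] = phage
    events["phage_censored"] = phage < 1.6
    return BeachSeason(
        site="testbeach",
        events=events,
        limits={"entero": 50.0, "phage": 1.6},
        transforms={"entero": "log10", "phage": "log10_plus1"},
    )


@pytest.fixture
def linear_frame() -> ModelFrame:
    """Noise-free linear response over 4 standardized covariates."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame(
        rng.standard_normal((40, 4)), columns=["a", "b", "c", "d"]
    )
    Z, params = standardize(X)
    y = 2.0 + 1.2 * Z["a"].to_numpy() - 0.7 * Z["c"].to_numpy()
    return ModelFrame(X=Z, y=y, standardization_params=params, site="s", indicator="i")
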