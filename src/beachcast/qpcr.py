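"""qPCR quantification and plate-level quality control.

Standard curves are fit by weighted linear regression of Ct on log10 copies
per reaction, compositing replicate measurements across instrument runs.
Amplification efficiency follows from the slope as 10**(-1/slope) - 1, and
the per-cycle amplification factor used by the delta-delta-Ct method is
amp_base = efficiency + 1 (close to, but not assumed to be, 2).

Two quantification routes are implemented:

* ``ddct_quantify`` — calibrator-anchored delta-delta Ct: the sample's
  target Ct is referenced to the mean calibrator target Ct, corrected by
  the sample-vs-calibrator difference in the Sketa22 (DNA recovery) assay,
  and scaled from the median calibrator copy number.  Results are
  calibrator sequence equivalents (CSE) or cell equivalents (CCE).
* ``curve_direct_quantify`` — direct inversion of the standard curve with
  an optional Sketa22 delta-Ct recovery adjustment (the E. coli route).

``run_qc`` applies the data-acceptance gates used to screen plates:
standard-curve parallelism across runs (ANCOVA), calibrator Ct windows,
Sketa22 and IAC control windows, a negative-control contamination check
against the LLQ, and a duplicate-Ct spread limit.  Undetected Ct values are
kept distinct from any number and substituted by 40 only inside averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StandardCurve",
    "QPCRRun",
    "QuantResult",
    "QCReport",
    "fit_composite_curve",
    "amplification_efficiency",
    "llq_per_sample",
    "ddct_quantify",
    "curve_direct_quantify",
    "calibrator_reference",
    "run_qc",
    "ancova_parallelism",
]

UNDETECTED_SENTINEL = "ND"
UNDETECTED_AVERAGING_CT = 40.0  # substituted for ND only when a mean is taken

DEFAULT_GATE_THRESHOLDS = {
    "ancova_alpha": 0.05,
    "calibrator_sd_window": 3.0,
    "sketa_window": 3.0,
    "iac_window": 1.5,
    "negative_llq": 720.0,
    "duplicate_ct_sd": 1.414,
}

GATE_NAMES = (
    "ancova",
    "calibrator_window",
    "sketa_window",
    "iac_window",
    "negative_llq",
    "duplicate_ct_spread",
)


def amplification_efficiency(slope: float) -> float:
    """Fractional per-cycle efficiency from a standard-curve slope.

    efficiency = 10**(-1/slope) - 1; a perfect doubling per cycle
    corresponds to slope -1/log10(2) ~ -3.32 and efficiency 1.0.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def llq_per_sample(llq_copies_per_reaction: float = 6.0, extract_fraction: float = 1.0 / 120.0) -> float:
    """Sample-level lower limit of quantification.

    The lowest quantifiable standard (copies per reaction) divided by the
    fraction of the DNA extract analyzed per reaction: 6 copies/reaction
    with 1/120 of the extract per reaction gives 720 copies/sample.
    """
    if extract_fraction <= 0:
        raise ValueError("extract fraction must be positive")
    return float(llq_copies_per_reaction / extract_fraction)


@dataclass
class StandardCurve:
    slope: float  # Ct per log10 copies, negative
    intercept: float  # Ct at 1 copy/reaction
    efficiency: float = field(init=False)
    amp_base: float = field(init=False)
    llq_copies_per_reaction: float = 6.0
    llq_ct: float = field(init=False)

    def __post_init__(self) -> None:
        self.efficiency = amplification_efficiency(self.slope)
        self.amp_base = self.efficiency + 1.0
        self.llq_ct = self.intercept + self.slope * np.log10(self.llq_copies_per_reaction)

    def ct_at(self, copies_per_reaction: float) -> float:
        return self.intercept + self.slope * np.log10(copies_per_reaction)

    def copies_at(self, ct: float) -> float:
        return float(10.0 ** ((ct - self.intercept) / self.slope))


def fit_composite_curve(
    log10_copies: Sequence[float],
    ct: Sequence[float],
    weights: Sequence[float] | str = "replicates",
    llq_copies_per_reaction: float = 6.0,
) -> StandardCurve:
    """Weighted linear regression of composited standard Ct measurements.

    ``weights="replicates"`` (the default) weights each standard level by
    its number of replicate Ct values, which on per-well data is the
    ordinary least-squares fit to the individual points; ``"equal"`` gives
    every level the same weight regardless of replication; an explicit
    per-point weight vector is also accepted.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    levels, counts = np.unique(x, return_counts=True)
    if len(levels) < 3:
        raise ValueError(f"need >= 3 distinct standard levels with numeric Ct, got {len(levels)}")
    if isinstance(weights, str):
        if weights == "replicates":
            w = np.ones_like(x)
        elif weights == "equal":
            per_level = dict(zip(levels, counts))
            w = np.array([1.0 / per_level[v] for v in x])
        else:
            raise ValueError("weights must be 'replicates', 'equal', or a vector")
    else:
        w = np.asarray(weights, dtype=float)[ok]
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    if slope >= 0:
        raise ValueError(f"fitted slope {slope:.3f} is non-negative: invalid standards")
    return StandardCurve(
        slope=slope, intercept=intercept, llq_copies_per_reaction=llq_copies_per_reaction
    )


@dataclass
class QPCRRun:
    """Long-format plate data plus per-run references and gate thresholds.

    ``wells`` columns: well, run_id, role in {standard, calibrator,
    negative, test}, assay in {target, IAC, Sketa22}, sample_id,
    log10_copies (nominal, standards only), ct (NaN encodes undetected).
    """

    wells: pd.DataFrame
    gate_thresholds: dict = field(default_factory=dict)

    def thresholds(self) -> dict:
        merged = dict(DEFAULT_GATE_THRESHOLDS)
        merged.update(self.gate_thresholds)
        return merged

    def subset(self, role: str | None = None, assay: str | None = None) -> pd.DataFrame:
        df = self.wells
        if role is not None:
            df = df[df["role"] == role]
        if assay is not None:
            df = df[df["assay"] == assay]
        return df

    def to_csv(self, path: str | Path) -> None:
        out = self.wells.copy()
        out["ct"] = out["ct"].map(
            lambda v: UNDETECTED_SENTINEL if pd.isna(v) else f"{v:.6g}"
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, gate_thresholds: dict | None = None) -> "QPCRRun":
        df = pd.read_csv(path, dtype={"ct": str})
        df["ct"] = df["ct"].map(
            lambda v: np.nan if (pd.isna(v) or str(v).strip() == UNDETECTED_SENTINEL) else float(v)
        )
        return cls(wells=df, gate_thresholds=gate_thresholds or {})


def _mean_ct_with_nd(ct: pd.Series) -> float:
    """Mean Ct where undetected wells enter as 40 (averaging convention)."""
    values = ct.fillna(UNDETECTED_AVERAGING_CT).to_numpy(float)
    return float(values.mean())


def calibrator_reference(run: QPCRRun, curve: StandardCurve) -> tuple[float, float, float]:
    """(mean calibrator target Ct, mean calibrator Sketa22 Ct, median
    calibrator copies per reaction derived from the curve)."""
    cal_t = run.subset("calibrator", "target")["ct"]
    cal_s = run.subset("calibrator", "Sketa22")["ct"]
    if cal_t.empty:
        raise ValueError("run has no calibrator target wells")
    median_copies = float(np.median([curve.copies_at(c) for c in cal_t.dropna()]))
    return _mean_ct_with_nd(cal_t), _mean_ct_with_nd(cal_s), median_copies


@dataclass
class QuantResult:
    copies_per_100ml: float
    log10_value: float
    below_llq: bool
    method: str


def ddct_quantify(
    sample_target_ct: float,
    sample_sketa_ct: float,
    run: QPCRRun,
    curve: StandardCurve,
    llq_copies_per_sample: float = 720.0,
    reactions_per_sample: float = 120.0,
    cce_factor: float = 1.0,
    sketa_adjust: bool = True,
) -> QuantResult:
    """Calibrator-anchored delta-delta-Ct quantification.

    ddCt = (sample target Ct - calibrator mean target Ct)
         - (sample Sketa22 Ct - calibrator mean Sketa22 Ct)
    copies/sample = median calibrator copies * reactions_per_sample
                    * amp_base**(-ddCt)

    ``cce_factor`` converts calibrator sequence equivalents to calibrator
    cell equivalents for the enterococci method (workbook constant,
    default 1).  An undetected target Ct yields a below-LLQ result.
    """
    cal_t, cal_s, med_copies = calibrator_reference(run, curve)
    if sample_target_ct is None or (isinstance(sample_target_ct, float) and np.isnan(sample_target_ct)):
        return QuantResult(np.nan, np.nan, True, "ddct")
    ddct = sample_target_ct - cal_t
    if sketa_adjust:
        if sample_sketa_ct is None or (isinstance(sample_sketa_ct, float) and np.isnan(sample_sketa_ct)):
            raise ValueError("Sketa22 Ct required for the recovery adjustment")
        ddct -= sample_sketa_ct - cal_s
    copies_sample = med_copies * reactions_per_sample * curve.amp_base ** (-ddct) * cce_factor
    below = copies_sample < llq_copies_per_sample
    return QuantResult(
        copies_per_100ml=float(copies_sample),
        log10_value=float(np.log10(copies_sample)) if copies_sample > 0 else np.nan,
        below_llq=bool(below),
        method="ddct",
    )


def curve_direct_quantify(
    target_ct: float,
    sketa_delta_ct: float,
    curve: StandardCurve,
    volume_scaling: float = 120.0,
    llq_copies_per_sample: float = 720.0,
) -> QuantResult:
    """Direct standard-curve quantification with a recovery adjustment.

    copies/reaction = 10**((Ct - intercept)/slope), multiplied by
    amp_base**(sketa delta Ct) — a sample whose Sketa22 Ct runs high
    relative to the calibrators lost DNA and is scaled up — then scaled to
    copies per 100 mL sample by ``volume_scaling`` (reactions per sample).
    """
    if volume_scaling <= 0:
        raise ValueError("volume_scaling must be positive")
    if target_ct is None or (isinstance(target_ct, float) and np.isnan(target_ct)):
        return QuantResult(np.nan, np.nan, True, "curve_direct")
    copies_rxn = curve.copies_at(target_ct) * curve.amp_base ** float(sketa_delta_ct)
    copies_sample = copies_rxn * volume_scaling
    return QuantResult(
        copies_per_100ml=float(copies_sample),
        log10_value=float(np.log10(copies_sample)) if copies_sample > 0 else np.nan,
        below_llq=bool(copies_sample < llq_copies_per_sample),
        method="curve_direct",
    )


def ancova_parallelism(curves: Sequence[tuple[Sequence[float], Sequence[float]]]) -> tuple[float, float]:
    """Nested-F parallelism test across per-run standard curves.

    p_slope compares separate-slopes against common-slope models; given a
    common slope, p_intercept compares separate-intercepts against a single
    line.  Large p-values mean the runs are consistent with one composite
    curve.  A zero incremental sum of squares (identical lines, possibly
    noiseless) returns p = 1 by convention.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 runs")
    xs, ys, gs = [], [], []
    for g, (x, y) in enumerate(curves):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(x)) < 3:
            raise ValueError(f"run {g}: need >= 3 distinct standard levels")
        xs.append(x)
        ys.append(y)
        gs.append(np.full(x.size, g))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(gs)
    n_runs = len(curves)
    run_dummies = np.column_stack([(g == i).astype(float) for i in range(1, n_runs)])

    def _rss(design: np.ndarray) -> tuple[float, int]:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid), design.shape[1]

    one = np.ones_like(x)
    rss1, p1 = _rss(np.column_stack([one, x]))  # single line
    rss2, p2 = _rss(np.column_stack([one, x, run_dummies]))  # common slope
    rss3, p3 = _rss(np.column_stack([one, x, run_dummies, run_dummies * x[:, None]]))

    def _nested_p(rss_small: float, df_small: int, rss_big: float, df_big: int) -> float:
        from scipy import stats

        df_num = df_big - df_small
        df_den = x.size - df_big
        delta = rss_small - rss_big
        scale = max(rss_small, 1.0)
        if delta <= 1e-12 * scale:
            return 1.0
        if rss_big <= 1e-12 * scale or df_den <= 0:
            return 0.0  # exact fit by the bigger model but not the smaller
        f = (delta / df_num) / (rss_big / df_den)
        return float(stats.f.sf(f, df_num, df_den))

    p_slope = _nested_p(rss2, p2, rss3, p3)
    p_intercept = _nested_p(rss1, p1, rss2, p2)
    return p_slope, p_intercept


@dataclass
class QCReport:
    gates: pd.DataFrame  # columns: gate, observed, threshold, passed (bool or NaN)

    @property
    def overall_pass(self) -> bool:
        evaluable = self.gates["passed"].dropna()
        return bool(evaluable.astype(bool).all())

    def failed_gates(self) -> list[str]:
        g = self.gates
        return list(g.loc[g["passed"] == False, "gate"])  # noqa: E712 (NaN-safe)

    def not_evaluable(self) -> list[str]:
        g = self.gates
        return list(g.loc[g["passed"].isna(), "gate"])


def run_qc(
    run: QPCRRun,
    curve: StandardCurve | None = None,
    curve_set: Sequence[tuple[Sequence[float], Sequence[float]]] | None = None,
) -> QCReport:
    """Apply the plate-acceptance gates; one pass/fail row per gate.

    Gates whose required controls are absent are reported not evaluable
    (passed = NaN) rather than silently passed; ``overall_pass`` is the
    conjunction over the evaluable gates.
    """
    thr = run.thresholds()
    rows = []

    def add(gate: str, observed: float | None, threshold: float, passed: bool | None) -> None:
        rows.append(
            {"gate": gate, "observed": np.nan if observed is None else float(observed),
             "threshold": float(threshold), "passed": passed if passed is None else bool(passed)}
        )

    # 1. standard-curve parallelism across instrument runs (ANCOVA)
    if curve_set is None:
        std = run.subset("standard", "target")
        curve_set = []
        for _, grp in std.groupby("run_id"):
            detected = grp[grp["ct"].notna()]
            curve_set.append(
                (detected["log10_copies"].to_numpy(float), detected["ct"].to_numpy(float))
            )
    alpha = thr["ancova_alpha"]
    try:
        p_slope, p_int = ancova_parallelism(curve_set)
        add("ancova", min(p_slope, p_int), alpha, min(p_slope, p_int) > alpha)
    except ValueError:
        add("ancova", None, alpha, None)

    # 2. calibrator target & Sketa22 Ct within +/- 3 SD of the reference means
    window = thr["calibrator_sd_window"]
    ref_keys = ("cal_target_mean", "cal_target_sd", "cal_sketa_mean", "cal_sketa_sd")
    cal_t = run.subset("calibrator", "target")["ct"]
    cal_s = run.subset("calibrator", "Sketa22")["ct"]
    if all(k in thr for k in ref_keys) and not cal_t.empty:
        zt = (cal_t.fillna(UNDETECTED_AVERAGING_CT) - thr["cal_target_mean"]) / thr["cal_target_sd"]
        zs = (cal_s.fillna(UNDETECTED_AVERAGING_CT) - thr["cal_sketa_mean"]) / thr["cal_sketa_sd"]
        worst = float(pd.concat([zt.abs(), zs.abs()]).max())
        add("calibrator_window", worst, window, worst <= window)
    else:
        add("calibrator_window", None, window, None)

    # 3. test-sample Sketa22 Ct within 3 units of the calibrator Sketa22 mean
    test_s = run.subset("test", "Sketa22")["ct"]
    if not test_s.empty and not cal_s.empty:
        dev = (test_s.fillna(UNDETECTED_AVERAGING_CT) - _mean_ct_with_nd(cal_s)).abs().max()
        add("sketa_window", float(dev), thr["sketa_window"], dev <= thr["sketa_window"])
    else:
        add("sketa_window", None, thr["sketa_window"], None)

    # 4. test-sample IAC Ct within 1.5 units of the negative-control IAC mean
    test_i = run.subset("test", "IAC")["ct"]
    neg_i = run.subset("negative", "IAC")["ct"]
    if not test_i.empty and not neg_i.empty:
        dev = (test_i.fillna(UNDETECTED_AVERAGING_CT) - _mean_ct_with_nd(neg_i)).abs().max()
        add("iac_window", float(dev), thr["iac_window"], dev <= thr["iac_window"])
    else:
        add("iac_window", None, thr["iac_window"], None)

    # 5. negative-control estimate < LLQ, prior to any Sketa22 adjustment;
    #    undetected Ct enters the average as 40
    neg_t = run.subset("negative", "target")["ct"]
    llq = thr["negative_llq"]
    if not neg_t.empty and curve is not None and not run.subset("calibrator", "target").empty:
        mean_ct = _mean_ct_with_nd(neg_t)
        est = ddct_quantify(
            mean_ct, np.nan, run, curve, llq_copies_per_sample=llq, sketa_adjust=False
        ).copies_per_100ml
        add("negative_llq", est, llq, est < llq)
    else:
        add("negative_llq", None, llq, None)

    # 6. duplicate target-Ct spread per test sample within 1.414
    test_t = run.subset("test", "target")
    if not test_t.empty and test_t.groupby("sample_id").size().max() >= 2:
        sds = (
            test_t.assign(ct=test_t["ct"].fillna(UNDETECTED_AVERAGING_CT))
            .groupby("sample_id")["ct"]
            .std(ddof=1)
            .dropna()
        )
        worst = float(sds.max()) if len(sds) else 0.0
        add("duplicate_ct_spread", worst, thr["duplicate_ct_sd"], worst <= thr["duplicate_ct_sd"])
    else:
        add("duplicate_ct_spread", None, thr["duplicate_ct_sd"], None)

    return QCReport(gates=pd.DataFrame(rows))
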