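"""Standard curves, delta-delta-Ct quantification and QC gates."""

import numpy as np
import pandas as pd
import pytest

from beachcast.qpcr import (
    QPCRRun,
    StandardCurve,
    amplification_efficiency,
    ancova_parallelism,
    calibrator_reference,
    curve_direct_quantify,
    ddct_quantify,
    fit_composite_curve,
    llq_per_sample,
    run_qc,
)
from beachcast.simulate import QPCRSimConfig, simulate_qpcr_run


class TestAmplificationEfficiency:
    @pytest.mark.parametrize(
        "slope, expected",
        [(-3.49, 0.93), (-3.58, 0.90), (-3.54, 0.92), (-1.0 / np.log10(2.0), 1.00)],
    )
    def test_known_slopes(self, slope, expected):
        assert round(amplification_efficiency(slope), 2) == expected

    def test_non_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            amplification_efficiency(0.1)

    def test_strictly_decreasing_in_slope_magnitude(self):
        slopes = -np.linspace(3.1, 4.0, 10)
        effs = [amplification_efficiency(s) for s in slopes]
        assert (np.diff(effs) < 0).all()


class TestFitCompositeCurve:
    def test_exact_points_recover_line(self):
        l10 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ct = 37.93 - 3.49 * l10
        curve = fit_composite_curve(l10, ct)
        assert curve.slope == pytest.approx(-3.49, abs=1e-10)
        assert curve.intercept == pytest.approx(37.93, abs=1e-10)
        assert curve.amp_base == pytest.approx(curve.efficiency + 1.0)
        assert curve.llq_ct == pytest.approx(37.93 - 3.49 * np.log10(6.0))

    def test_duplicated_points_equal_doubled_weights(self):
        rng = np.random.default_rng(0)
        l10 = np.array([1.0, 2.0, 3.0, 4.0])
        ct = 38.0 - 3.4 * l10 + rng.normal(0, 0.2, 4)
        dup = fit_composite_curve(np.tile(l10, 2), np.tile(ct, 2), weights="replicates")
        weighted = fit_composite_curve(l10, ct, weights=2.0 * np.ones(4))
        assert dup.slope == pytest.approx(weighted.slope, abs=1e-10)
        assert dup.intercept == pytest.approx(weighted.intercept, abs=1e-10)

    def test_matches_closed_form_wls_oracle(self):
        rng = np.random.default_rng(1)
        l10 = np.repeat([0.78, 1.78, 2.78, 3.78, 4.78], 3)
        ct = 37.9 - 3.5 * l10 + rng.normal(0, 0.3, l10.size)
        w = rng.uniform(0.5, 2.0, l10.size)
        curve = fit_composite_curve(l10, ct, weights=w)
        # normal-equations oracle for weighted least squares
        A = np.column_stack([np.ones_like(l10), l10])
        beta = np.linalg.solve(A.T @ (w[:, None] * A), A.T @ (w * ct))
        assert curve.intercept == pytest.approx(beta[0], abs=1e-10)
        assert curve.slope == pytest.approx(beta[1], abs=1e-10)

    def test_fewer_than_three_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_composite_curve([1.0, 1.0, 2.0], [34.0, 34.1, 31.0])

    def test_rising_ct_with_copies_rejected(self):
        l10 = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="non-negative"):
            fit_composite_curve(l10, 30.0 + 3.0 * l10)


class TestQuantification:
    @pytest.fixture
    def noiseless_run(self):
        return simulate_qpcr_run(QPCRSimConfig(ct_noise_sd=0.0, seed=1))

    @pytest.fixture
    def curve(self, noiseless_run):
        std = noiseless_run.subset("standard", "target")
        return fit_composite_curve(std["log10_copies"], std["ct"])

    def test_ddct_identity_at_zero_delta(self, noiseless_run, curve):
        cal_t, cal_s, med = calibrator_reference(noiseless_run, curve)
        res = ddct_quantify(cal_t, cal_s, noiseless_run, curve, reactions_per_sample=1.0)
        assert res.copies_per_100ml == pytest.approx(med)

    def test_ddct_one_cycle_doubles_with_base_two(self, noiseless_run):
        curve2 = StandardCurve(slope=-1.0 / np.log10(2.0), intercept=37.0)
        assert curve2.amp_base == pytest.approx(2.0)
        cal_t, cal_s, med = calibrator_reference(noiseless_run, curve2)
        res = ddct_quantify(cal_t - 1.0, cal_s, noiseless_run, curve2,
                            reactions_per_sample=1.0)
        assert res.copies_per_100ml == pytest.approx(2.0 * med)

    def test_ddct_agrees_with_curve_direct_on_noiseless_well(self, noiseless_run, curve):
        """With zero Sketa delta and calibrator copies taken from the
        curve, the two quantification routes coincide."""
        cal_t, cal_s, _ = calibrator_reference(noiseless_run, curve)
        target_ct = curve.ct_at(500.0)
        via_ddct = ddct_quantify(target_ct, cal_s, noiseless_run, curve,
                                 reactions_per_sample=120.0)
        direct = curve_direct_quantify(target_ct, 0.0, curve, volume_scaling=120.0)
        assert via_ddct.copies_per_100ml / direct.copies_per_100ml == pytest.approx(
            1.0, abs=1e-6
        )

    def test_curve_definition_anchors(self):
        curve = StandardCurve(slope=-3.49, intercept=37.93)
        one = curve_direct_quantify(curve.intercept, 0.0, curve, volume_scaling=1.0)
        ten = curve_direct_quantify(curve.intercept + curve.slope, 0.0, curve,
                                    volume_scaling=1.0)
        assert one.copies_per_100ml == pytest.approx(1.0)
        assert ten.copies_per_100ml == pytest.approx(10.0)

    def test_sample_level_llq_from_extract_fraction(self):
        assert llq_per_sample(6.0, 1.0 / 120.0) == pytest.approx(720.0)

    def test_round_trip_is_exact(self):
        curve = StandardCurve(slope=-3.54, intercept=37.88)
        for copies in (6.0, 720.0, 1.0e5):
            res = curve_direct_quantify(curve.ct_at(copies), 0.0, curve,
                                        volume_scaling=1.0)
            assert res.copies_per_100ml == pytest.approx(copies, rel=1e-12)

    def test_lower_ct_means_more_copies(self):
        curve = StandardCurve(slope=-3.49, intercept=37.93)
        cts = np.linspace(20, 36, 9)
        copies = [curve_direct_quantify(c, 0.0, curve).copies_per_100ml for c in cts]
        assert (np.diff(copies) < 0).all()

    def test_undetected_target_reports_below_llq(self, noiseless_run, curve):
        res = ddct_quantify(np.nan, 24.0, noiseless_run, curve)
        assert res.below_llq and np.isnan(res.copies_per_100ml)

    def test_below_llq_flag_tracks_threshold(self):
        curve = StandardCurve(slope=-3.49, intercept=37.93)
        low = curve_direct_quantify(curve.ct_at(5.0), 0.0, curve,
                                    volume_scaling=120.0)
        high = curve_direct_quantify(curve.ct_at(7.0), 0.0, curve,
                                     volume_scaling=120.0)
        assert low.below_llq and not high.below_llq  # 600 < 720 < 840


class TestRunQC:
    GATES = ["ancova", "calibrator_window", "sketa_window", "iac_window",
             "negative_llq", "duplicate_ct_spread"]

    @staticmethod
    def _qc(inject=()):
        run = simulate_qpcr_run(QPCRSimConfig(ct_noise_sd=0.0, seed=1,
                                              inject_failures=tuple(inject)))
        std = run.subset("standard", "target")
        curve = fit_composite_curve(std["log10_copies"], std["ct"])
        return run_qc(run, curve=curve)

    def test_on_nominal_controls_pass_every_gate(self):
        report = self._qc()
        assert report.overall_pass
        assert report.gates["passed"].astype(bool).all()

    @pytest.mark.parametrize("gate", GATES)
    def test_each_injected_violation_flips_exactly_its_own_gate(self, gate):
        report = self._qc([gate])
        assert report.failed_gates() == [gate]
        assert not report.overall_pass

    def test_iac_shift_observed_statistic_matches_threshold_story(self):
        report = self._qc(["iac_window"])
        row = report.gates.set_index("gate").loc["iac_window"]
        assert row["observed"] == pytest.approx(2.0)
        assert row["threshold"] == 1.5

    def test_duplicate_spread_gate_trips_above_limit(self):
        # duplicate Cts 5 apart -> sd ~3.54, far beyond the 1.414 limit
        report = self._qc(["duplicate_ct_spread"])
        row = report.gates.set_index("gate").loc["duplicate_ct_spread"]
        assert row["observed"] > 1.414

    def test_missing_controls_reported_not_evaluable_never_passed(self):
        run = simulate_qpcr_run(QPCRSimConfig(ct_noise_sd=0.0, seed=2))
        run.wells = run.wells[run.wells["role"] != "negative"]
        std = run.subset("standard", "target")
        curve = fit_composite_curve(std["log10_copies"], std["ct"])
        report = run_qc(run, curve=curve)
        assert "iac_window" in report.not_evaluable()
        assert "negative_llq" in report.not_evaluable()
        evaluable = report.gates.dropna(subset=["passed"])
        assert evaluable["passed"].astype(bool).all()

    def test_undetected_negatives_average_as_forty(self):
        """The ND -> 40 averaging convention: the negative-control gate's
        estimate equals the ddCt estimate computed at Ct 40."""
        run = simulate_qpcr_run(QPCRSimConfig(ct_noise_sd=0.0, seed=3))
        std = run.subset("standard", "target")
        curve = fit_composite_curve(std["log10_copies"], std["ct"])
        report = run_qc(run, curve=curve)
        observed = report.gates.set_index("gate").loc["negative_llq", "observed"]
        expected = ddct_quantify(40.0, np.nan, run, curve, sketa_adjust=False)
        assert observed == pytest.approx(expected.copies_per_100ml)


class TestAncovaParallelism:
    @staticmethod
    def _standards(slope, intercept, noise_sd, seed, reps=2):
        rng = np.random.default_rng(seed)
        l10 = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], reps)
        return l10, intercept + slope * l10 + rng.normal(0, noise_sd, l10.size)

    def test_identical_noiseless_lines_give_p_one(self):
        a = self._standards(-3.5, 38.0, 0.0, 0)
        b = self._standards(-3.5, 38.0, 0.0, 1)
        p_slope, p_int = ancova_parallelism([a, b])
        assert p_slope == 1.0 and p_int == 1.0

    def test_clearly_different_slopes_detected(self):
        a = self._standards(-3.2, 38.0, 0.05, 2)
        b = self._standards(-3.9, 38.0, 0.05, 3)
        p_slope, _ = ancova_parallelism([a, b])
        assert p_slope < 0.05

    def test_matches_statsmodels_nested_f_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        a = self._standards(-3.5, 38.0, 0.3, 4)
        b = self._standards(-3.4, 37.6, 0.3, 5)
        p_slope, p_int = ancova_parallelism([a, b])
        df = pd.DataFrame({
            "x": np.concatenate([a[0], b[0]]),
            "ct": np.concatenate([a[1], b[1]]),
            "run": ["a"] * a[0].size + ["b"] * b[0].size,
        })
        m1 = ols("ct ~ x", df).fit()
        m2 = ols("ct ~ x + C(run)", df).fit()
        m3 = ols("ct ~ x * C(run)", df).fit()
        p_slope_sm = sm.stats.anova_lm(m2, m3)["Pr(>F)"].iloc[1]
        p_int_sm = sm.stats.anova_lm(m1, m2)["Pr(>F)"].iloc[1]
        assert p_slope == pytest.approx(p_slope_sm, abs=1e-8)
        assert p_int == pytest.approx(p_int_sm, abs=1e-8)

    def test_insufficient_runs_or_levels_rejected(self):
        a = self._standards(-3.5, 38.0, 0.1, 0)
        with pytest.raises(ValueError):
            ancova_parallelism([a])
        with pytest.raises(ValueError):
            ancova_parallelism([a, (np.array([1.0, 1.0, 2.0]), np.array([34.0, 34.2, 31.0]))])


class TestRunSerialization:
    def test_nd_sentinel_round_trip(self, tmp_path):
        run = simulate_qpcr_run(QPCRSimConfig(ct_noise_sd=0.1, seed=7))
        path = tmp_path / "run.csv"
        run.to_csv(path)
        text = path.read_text()
        assert "ND" in text  # undetected negatives
        back = QPCRRun.from_csv(path)
        assert back.wells["ct"].isna().sum() == run.wells["ct"].isna().sum()
        np.testing.assert_allclose(
            back.wells["ct"].dropna().to_numpy(),
            run.wells["ct"].dropna().round(5).to_numpy(),
            atol=1e-4,
        )
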