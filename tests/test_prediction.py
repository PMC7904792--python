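"""Van't Hoff fits, elution-temperature interpolation and RI prediction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cpgc import (
    AlkaneLadder,
    CalibrationError,
    ColumnElutionModel,
    GeneratorConfig,
    NoCrossingError,
    OutOfRangeError,
    TemperatureProgram,
    VantHoffFit,
    aggregate_diastereomers,
    calibrate_characteristic_logK,
    elution_temperature,
    empirical_correction,
    fit_vant_hoff,
    make_cp_peaks,
    make_logk_tables,
    predicted_ri,
)
from cpgc.prediction import fit_logk_table, predict_ri_table

PROGRAM = TemperatureProgram.from_celsius(70, 1.0, 10, 280, 10)


def _model(logk_star=4.0, carbons=(12, 13, 14), temps=(420.0, 444.0, 470.0)):
    return ColumnElutionModel(
        column_id="col", program=PROGRAM, characteristic_logk=logk_star,
        alkane_carbons=carbons, alkane_temps=temps,
    )


class TestVantHoff:
    def test_two_point_line(self):
        fit = fit_vant_hoff([400.0, 500.0], [5.0, 3.0])
        assert fit.slope == pytest.approx(4000)
        assert fit.intercept == pytest.approx(-5.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_logk_zero_slope(self):
        fit = fit_vant_hoff([400.0, 450.0, 500.0], [2.5, 2.5, 2.5])
        assert fit.slope == pytest.approx(0, abs=1e-12)

    def test_exact_five_point_recovery(self):
        T = np.linspace(373.15, 573.15, 5)
        fit = fit_vant_hoff(T, 5200.0 / T - 7.3)
        assert fit.slope == pytest.approx(5200, rel=1e-9)
        assert fit.intercept == pytest.approx(-7.3, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            fit_vant_hoff([400.0, -10.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="singular"):
            fit_vant_hoff([400.0, 400.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_vant_hoff([400.0], [1.0])


class TestElutionTemperature:
    def test_inverts_the_line(self):
        fit = VantHoffFit(slope=4000, intercept=-5.0)
        assert elution_temperature(fit, _model()) == pytest.approx(4000 / 9)

    def test_on_curve_point(self):
        fit = fit_vant_hoff([400.0, 500.0], [5.0, 3.0])
        model = _model(logk_star=5.0)  # logK at 400 K is exactly 5
        assert elution_temperature(fit, model) == pytest.approx(400.0)

    def test_zero_slope_no_crossing(self):
        with pytest.raises(NoCrossingError):
            elution_temperature(VantHoffFit(0.0, -5.0), _model())
        with pytest.raises(NoCrossingError):
            elution_temperature(VantHoffFit(4000.0, 4.0), _model(logk_star=4.0))

    def test_hold_clamping_warns(self):
        hot = VantHoffFit(slope=9000, intercept=-5.0)  # crossing at 1000 K
        with pytest.warns(UserWarning, match="clamped"):
            t = elution_temperature(hot, _model())
        assert t == PROGRAM.tmax_k


class TestCharacteristicLogK:
    def test_forward_constructed_exact(self):
        star = 2.0
        ladder = AlkaneLadder((12, 13, 14), (8.0, 10.0, 12.0), "col")
        fits = []
        for n, rt in zip(ladder.carbon_numbers, ladder.retention_times):
            T = PROGRAM.temperature_at(rt)
            slope = 4000.0 + 150 * n
            fits.append((n, VantHoffFit(slope, star - slope / T)))
        assert calibrate_characteristic_logK(fits, ladder, PROGRAM) == pytest.approx(
            star, abs=1e-6
        )

    def test_single_alkane_solved_exactly(self):
        ladder = AlkaneLadder((12, 13), (8.0, 10.0), "col")
        fit = VantHoffFit(5000.0, -6.0)
        star = calibrate_characteristic_logK([(12, fit)], ladder, PROGRAM)
        assert star == pytest.approx(fit.logk_at(PROGRAM.temperature_at(8.0)))

    def test_inconsistent_alkanes_least_squares(self):
        ladder = AlkaneLadder((12, 13, 14), (8.0, 10.0, 12.0), "col")
        star = 2.0
        fits = []
        for i, (n, rt) in enumerate(zip(ladder.carbon_numbers,
                                        ladder.retention_times)):
            T = PROGRAM.temperature_at(rt) + (-5.0 if i % 2 else 5.0)
            slope = 4500.0
            fits.append((n, VantHoffFit(slope, star - slope / T)))
        est = calibrate_characteristic_logK(fits, ladder, PROGRAM)

        def objective(x):
            ts = np.array([f.slope / (x - f.intercept) for _, f in fits])
            targets = np.array(
                [PROGRAM.temperature_at(rt) for rt in ladder.retention_times]
            )
            return ((ts - targets) ** 2).sum()

        lo = min(f.logk_at(PROGRAM.tmax_k) for _, f in fits)
        hi = max(f.logk_at(PROGRAM.t0_k) for _, f in fits)
        assert objective(est) <= objective(lo) + 1e-9
        assert objective(est) <= objective(hi) + 1e-9


class TestPredictedRI:
    def test_exact_at_alkane_and_midpoint(self):
        model = _model()
        # crossing exactly at C12's elution temperature
        fit12 = VantHoffFit(4200.0, model.characteristic_logk - 4200.0 / 420.0)
        assert predicted_ri(fit12, model) == 1200.0
        mid = (420.0 + 444.0) / 2
        fit_mid = VantHoffFit(4200.0, model.characteristic_logk - 4200.0 / mid)
        assert predicted_ri(fit_mid, model) == pytest.approx(1250.0)

    def test_outside_alkane_span(self):
        model = _model()
        low = VantHoffFit(4200.0, model.characteristic_logk - 4200.0 / 400.0)
        with pytest.raises(OutOfRangeError):
            predicted_ri(low, model)

    def test_generator_round_trip_within_one_unit(self):
        cfg = GeneratorConfig(seed=3, ri_noise_sd=0.0, diastereomer_spread=25.0)
        cp = make_cp_peaks(["2,5,6,9-C10Cl4", "1,1,1,3,9,10-C10Cl6"], cfg)
        logk = make_logk_tables(
            cp.isomer_truth.rename(columns={"ri": "target_ri"}), cfg
        )
        checked = 0
        for col, table in logk.tables.items():
            fits = fit_logk_table(table)
            model = logk.models[col]
            sel = logk.targets[logk.targets.column_id == col]
            for _, r in sel.iterrows():
                fit = fits[(r.compound_id, r.stereoisomer_id)]
                with warnings.catch_warnings():
                    warnings.simplefilter("error")  # no clamping expected
                    ri = predicted_ri(fit, model)
                assert abs(ri - r.target_ri) < 1.0
                checked += 1
        assert checked > 50

    def test_alkane_self_consistency(self):
        # an alkane predicted against a model built from its own pathway
        cfg = GeneratorConfig(seed=3, ri_noise_sd=0.0)
        cp = make_cp_peaks(["1,1,1,3-C10Cl4"], cfg)
        logk = make_logk_tables(
            cp.isomer_truth.rename(columns={"ri": "target_ri"}), cfg
        )
        col = "SPB-Octyl"
        fits = fit_logk_table(logk.tables[col])
        model = logk.models[col]
        for n in model.alkane_carbons[1:-1]:
            assert predicted_ri(fits[(f"C{n}", "")], model) == pytest.approx(
                100.0 * n, abs=1e-9
            )


class TestAggregation:
    def test_two_diastereomer_example(self):
        mean, rng = aggregate_diastereomers([2304.0, 2721.0])
        assert mean == pytest.approx(2512.5)
        assert rng == pytest.approx(417.0)

    @pytest.mark.parametrize("values, expected", [
        ([1500.0], (1500.0, 0.0)),
        ([1300.0] * 4, (1300.0, 0.0)),
    ])
    def test_degenerate_lists(self, values, expected):
        assert aggregate_diastereomers(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_diastereomers([])


class TestEmpiricalCorrection:
    def test_identity_line(self):
        pairs = [(1000.0, 1000.0), (1500.0, 1500.0), (2000.0, 2000.0)]
        res = empirical_correction(pairs)
        assert res.alpha == pytest.approx(1.0)
        assert res.beta == pytest.approx(0.0, abs=1e-9)
        assert res.rmse_after == pytest.approx(res.rmse_before, abs=1e-9)

    def test_exact_affine_recovery(self):
        pred = np.array([1000.0, 1400.0, 1900.0, 2500.0])
        pairs = list(zip(pred, 0.8 * pred + 300.0))
        res = empirical_correction(pairs)
        assert res.alpha == pytest.approx(0.8)
        assert res.beta == pytest.approx(300.0)
        assert res.rmse_after == pytest.approx(0.0, abs=1e-9)
        assert res.rmse_before > 0

    def test_never_increases_rmse(self):
        rng = np.random.default_rng(11)
        pred = rng.uniform(1000, 3000, 30)
        meas = 0.9 * pred + 150 + rng.normal(0, 40, 30)
        res = empirical_correction(list(zip(pred, meas)))
        assert res.rmse_after <= res.rmse_before + 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            empirical_correction([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError, match="singular"):
            empirical_correction([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


def test_predict_ri_table_end_to_end():
    cfg = GeneratorConfig(seed=9, ri_noise_sd=0.0, diastereomer_spread=30.0)
    cp = make_cp_peaks(["2,5,6,9-C10Cl4"], cfg)
    logk = make_logk_tables(cp.isomer_truth.rename(columns={"ri": "target_ri"}), cfg)
    col = "DB-225ms"
    out = predict_ri_table(
        logk.tables[col],
        cfg.column(col).program,
        characteristic_logk=None,
        measured_ladder=cp.ladders[col],
        column_id=col,
    )
    row = out[out.compound_id == "2,5,6,9-C10Cl4"].iloc[0]
    truth = cp.isomer_truth.query("column_id == @col")["ri"]
    assert row["n_isomers"] == 6
    assert row["ri_mean"] == pytest.approx(truth.mean(), abs=1.0)
    assert row["ri_range"] == pytest.approx(truth.max() - truth.min(), abs=1.0)
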