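"""Prediction-error metric, fold classification, bands and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainecf import (
    ObservationSeries,
    PEReport,
    PredictionBand,
    TWOFOLD_PE,
    bandwidth_predictions,
    evaluate_predictions,
    fold_class,
    fold_threshold,
    median_pe,
    prediction_error,
    simulate_brain_ecf,
    summarize_within_twofold,
)

conc = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


def obs_series(times, values, animals=None):
    n = len(times)
    return ObservationSeries(
        drug="probe",
        regimen_class="short",
        data=pd.DataFrame(
            {
                "animal_id": animals if animals is not None else [1] * n,
                "time_min": times,
                "conc_ng_per_mL": values,
            }
        ),
        provenance="synthetic",
    )


class TestPredictionError:
    @pytest.mark.parametrize(
        "pred,obs,expected",
        [(5.0, 5.0, 0.0), (2.0, 1.0, 2 / 3), (1.0, 2.0, -2 / 3)],
    )
    def test_values(self, pred, obs, expected):
        assert prediction_error(pred, obs) == pytest.approx(expected)

    def test_twofold_bound_prints_as_067(self):
        assert round(abs(prediction_error(2.0, 1.0)), 2) == 0.67

    def test_zero_observation_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(1.0, 0.0)

    @settings(max_examples=500, deadline=None)
    @given(a=conc, b=conc)
    def test_antisymmetry_and_bounds(self, a, b):
        pe = prediction_error(a, b)
        assert -2.0 < pe < 2.0
        assert pe == pytest.approx(-prediction_error(b, a), rel=1e-9, abs=1e-12)


class TestFoldThreshold:
    @pytest.mark.parametrize("k,expected", [(1, 0.0), (2, 2 / 3), (3, 1.0), (5, 4 / 3)])
    def test_closed_form(self, k, expected):
        assert fold_threshold(k) == pytest.approx(expected)

    def test_subunity_fold_rejected(self):
        with pytest.raises(ValueError):
            fold_threshold(0.5)

    @settings(max_examples=200, deadline=None)
    @given(k=st.floats(1.0, 100.0), dk=st.floats(0.01, 10.0))
    def test_strictly_increasing(self, k, dk):
        assert fold_threshold(k + dk) > fold_threshold(k)

    @settings(max_examples=200, deadline=None)
    @given(k=st.floats(1.0, 50.0))
    def test_constant_ratio_series_hits_threshold_exactly(self, k):
        obs = obs_series([10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        preds = k * obs.concentrations
        assert median_pe(preds, obs) == pytest.approx(fold_threshold(k), rel=1e-12)

    def test_fold_classification_bands(self):
        assert fold_class(0.1) == "<2-fold"
        assert fold_class(2 / 3) == "<3-fold"  # half-open at the twofold edge
        assert fold_class(1.1) == "<5-fold"
        assert fold_class(1.5) == ">=5-fold"


class TestMedianPE:
    def test_order_statistic(self):
        obs = obs_series([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        preds = np.array([0.905, 1.105, 1.822])  # PEs about -0.1, 0.1, 0.6
        assert median_pe(preds, obs) == pytest.approx(0.1, abs=0.01)

    def test_doubled_predictions(self):
        obs = obs_series([1.0, 2.0], [3.0, 7.0])
        assert median_pe(2 * obs.concentrations, obs) == pytest.approx(2 / 3)

    def test_per_animal_option(self):
        obs = obs_series([1, 2, 1, 2], [1, 1, 1, 1], animals=[1, 1, 2, 2])
        preds = np.array([2.0, 2.0, 0.5, 0.5])  # animal medians +2/3 and -2/3
        assert median_pe(preds, obs, per_animal=True) == pytest.approx(0.0)

    def test_misaligned_predictions_rejected(self):
        obs = obs_series([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            median_pe(np.array([1.0]), obs)


class TestObservationValidation:
    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            obs_series([1.0], [0.0])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ObservationSeries("x", "short", pd.DataFrame({"time_min": [1.0]}))


class TestEvaluateAgainstSimulation:
    def test_noise_free_self_evaluation_is_exact(self, bundle, grid240):
        from brainecf import build_spec

        spec = build_spec(bundle, "morphine", "short", cell_line="Caco-2")
        res = simulate_brain_ecf(spec, grid240)
        times = np.arange(20.0, 241.0, 20.0)
        obs = obs_series(list(times), list(res.ecf_at(times)))
        report = evaluate_predictions(res, obs, keys={"drug": "morphine"})
        assert report.median_pe == pytest.approx(0.0, abs=1e-9)
        assert report.within_twofold()


class TestBandwidth:
    def test_band_ordering_and_degeneracy(self, bundle):
        from brainecf import build_spec
        from brainecf.scenarios import resolve_record

        grid = np.linspace(0.0, 240.0, 121)
        # three expression levels: ordered envelope, highest expression on top
        record = resolve_record(bundle, "quinidine", "MDCKII-MDR1", "Feng2008")
        template = build_spec(
            bundle, "quinidine", "short", cell_line="MDCKII-MDR1",
            source="Feng2008", expression_level="no_ref",
        )
        band = bandwidth_predictions(
            template, record, bundle.expression_records("MDCKII-MDR1"),
            bundle.expr_in_vivo, grid,
        )
        assert np.all(band.lower <= band.central + 1e-12)
        assert np.all(band.central <= band.upper + 1e-12)
        assert set(band.levels) == {"highest", "average", "lowest"}

        # LLC-PK1-MDR1 reports a single expression value: degenerate band
        record = resolve_record(bundle, "quinidine", "LLC-PK1-MDR1", "Nagaya2020")
        template = build_spec(
            bundle, "quinidine", "short", cell_line="LLC-PK1-MDR1",
            expression_level="no_ref",
        )
        band = bandwidth_predictions(
            template, record, bundle.expression_records("LLC-PK1-MDR1"),
            bundle.expr_in_vivo, grid,
        )
        assert band.lower == pytest.approx(band.upper)

    def test_no_ref_band_is_single_curve(self, bundle):
        from brainecf import build_spec
        from brainecf.scenarios import resolve_record

        grid = np.linspace(0.0, 240.0, 61)
        record = resolve_record(bundle, "quinidine", "MDCKII-MDR1", "Feng2008")
        template = build_spec(
            bundle, "quinidine", "short", cell_line="MDCKII-MDR1",
            source="Feng2008", expression_level="no_ref",
        )
        band = bandwidth_predictions(
            template, record, bundle.expression_records("MDCKII-MDR1"),
            bundle.expr_in_vivo, grid, no_ref=True,
        )
        assert band.levels == {"no_ref": 1.0}
        assert band.lower == pytest.approx(band.upper)

    def test_disordered_band_rejected(self):
        with pytest.raises(ValueError):
            PredictionBand(
                time=np.array([0.0, 1.0]),
                lower=np.array([1.0, 1.0]),
                central=np.array([0.5, 0.5]),
                upper=np.array([2.0, 2.0]),
                levels={},
            )


class TestStratification:
    @staticmethod
    def report(median, **keys):
        return PEReport(np.array([median]), median, fold_class(median), keys)

    def test_fraction_within_twofold(self):
        reports = [self.report(0.5, drug="a"), self.report(0.9, drug="a")]
        table = summarize_within_twofold(reports, ["drug"])
        assert table.loc[0, "percent_within"] == pytest.approx(50.0)
        assert table.loc[0, "n"] == 2

    def test_all_perfect(self):
        reports = [self.report(0.0, drug="a"), self.report(0.0, drug="b")]
        table = summarize_within_twofold(reports, ["drug"])
        assert (table["percent_within"] == 100.0).all()

    def test_two_key_stratification_partitions(self):
        reports = [
            self.report(0.1, drug="a", cell_line="x"),
            self.report(0.8, drug="a", cell_line="y"),
            self.report(0.2, drug="b", cell_line="x"),
        ]
        table = summarize_within_twofold(reports, ["drug", "cell_line"])
        assert table["n"].sum() == len(reports)

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            summarize_within_twofold([self.report(0.1, drug="a")], ["cell_line"])
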