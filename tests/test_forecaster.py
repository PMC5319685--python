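"""End-to-end pipeline tests.

Most tests here run with a reduced swarm and training budget so the suite
stays fast; the full default study conditions are exercised in the
acceptance tests.
"""

import numpy as np
import pytest

from emdcast import forecaster, metrics
from emdcast.errors import InvalidInputError
from emdcast.mlp import TrainConfig
from emdcast.pso import PSOConfig
from emdcast.series import TimeSeries

SMALL = dict(
    train_config=TrainConfig(max_epochs=150),
    pso_config=PSOConfig(population=12, iterations=30),
)


class TestSplitByDate:
    def test_nine_year_series_split(self, default_series):
        train, test = forecaster.split_by_date(default_series, (2012, 11))
        assert len(train) == 95 and len(test) == 13
        assert train.end == (2012, 11)
        assert test.start == (2012, 12) and test.end == (2013, 12)

    def test_penultimate_split(self, default_series):
        _, test = forecaster.split_by_date(default_series, (2013, 11))
        assert len(test) == 1

    def test_boundary_splits_rejected(self, default_series):
        with pytest.raises(InvalidInputError):
            forecaster.split_by_date(default_series, (2013, 12))  # no test left
        with pytest.raises(InvalidInputError):
            forecaster.split_by_date(default_series, (2005, 1))  # no train left
        with pytest.raises(InvalidInputError):
            forecaster.split_by_date(default_series, (2004, 6))  # out of range

    def test_lengths_sum(self, default_series):
        train, test = forecaster.split_by_date(default_series, (2010, 6))
        assert len(train) + len(test) == len(default_series)


class TestFit:
    def test_bpann_has_one_component(self, default_series):
        model = forecaster.fit(default_series, (2012, 11), "bpann", seed=0, **SMALL)
        assert model.n_components == 1
        assert model.decomposition is None

    def test_emd_mode_one_model_per_component(self, default_series):
        model = forecaster.fit(
            default_series, (2012, 11), "emd_pso_bpann", seed=0, **SMALL
        )
        assert model.decomposition is not None
        assert model.n_components == model.decomposition.n_imfs + 1

    def test_refined_mse_never_exceeds_pso_fitness(self, default_series):
        model = forecaster.fit(
            default_series, (2012, 11), "emd_pso_bpann", seed=1, **SMALL
        )
        for refined, swarm_best in zip(
            model.component_train_mse, model.pso_best_fitness
        ):
            assert refined <= swarm_best + 1e-12

    def test_unknown_mode_rejected(self, default_series):
        with pytest.raises(InvalidInputError):
            forecaster.fit(default_series, (2012, 11), "arima")

    def test_train_scope_is_leakage_free(self, default_series):
        """Altering test-period values must not change a train-scoped fit."""
        altered = default_series.values.copy()
        altered[95:] *= 1.5
        other = TimeSeries(altered, default_series.start)
        kwargs = dict(decompose_scope="train", seed=3, **SMALL)
        for mode in ("bpann", "emd_pso_bpann"):
            m1 = forecaster.fit(default_series, (2012, 11), mode, **kwargs)
            m2 = forecaster.fit(other, (2012, 11), mode, **kwargs)
            for (p1, _), (p2, _) in zip(m1.component_models, m2.component_models):
                assert np.array_equal(p1.to_vector(), p2.to_vector())


@pytest.fixture(scope="module")
def fitted(default_series):
    return forecaster.fit(default_series, (2012, 11), "emd_pso_bpann", seed=0, **SMALL)


class TestPredict:
    def test_superposition_identity(self, fitted, default_series):
        report = forecaster.predict(fitted, default_series, (2012, 12), (2013, 12))
        assert np.max(
            np.abs(report.predicted - report.per_component_predicted.sum(axis=1))
        ) < 1e-9

    def test_horizon_labels_and_lengths(self, fitted, default_series):
        report = forecaster.predict(fitted, default_series, (2012, 12), (2013, 12))
        assert len(report.predicted) == 13
        assert report.horizon_labels[0] == (2012, 12)
        assert report.horizon_labels[-1] == (2013, 12)
        assert np.array_equal(report.observed, default_series.values[95:])

    def test_schemes_agree_on_first_step(self, fitted, default_series):
        one = forecaster.predict(
            fitted, default_series, (2012, 12), (2013, 12), "one_step_ahead"
        )
        rec = forecaster.predict(
            fitted, default_series, (2012, 12), (2013, 12), "recursive"
        )
        # the first horizon step has only observed lags under both schemes
        assert one.predicted[0] == pytest.approx(rec.predicted[0])

    def test_metrics_recomputable_from_predictions(self, fitted, default_series):
        report = forecaster.predict(fitted, default_series, (2012, 12), (2013, 12))
        assert report.metrics.MAPE == pytest.approx(
            metrics.mape(report.predicted, report.observed)
        )
        assert report.metrics.SSE == pytest.approx(
            metrics.sse(report.predicted, report.observed)
        )

    def test_bad_horizons_rejected(self, fitted, default_series):
        with pytest.raises(InvalidInputError):
            forecaster.predict(fitted, default_series, (2005, 2), (2005, 3))  # no lags
        with pytest.raises(InvalidInputError):
            forecaster.predict(fitted, default_series, (2013, 12), (2014, 6))
        with pytest.raises(InvalidInputError):
            forecaster.predict(fitted, default_series, (2013, 6), (2013, 1))


def test_end_to_end_determinism(default_series):
    runs = [
        forecaster.fit_predict(
            default_series, (2012, 11), "emd_pso_bpann", seed=7, **SMALL
        )[1]
        for _ in range(2)
    ]
    assert np.array_equal(runs[0].predicted, runs[1].predicted)
    assert runs[0].metrics == runs[1].metrics


class TestCompareMethods:
    def test_single_method_single_seed(self, default_series):
        table = forecaster.compare_methods(
            default_series, (2012, 11), methods=["bpann"], seeds=[0], **SMALL
        )
        assert len(table) == 1
        assert set(table.columns) == {"method", "seed", "R", "RMSE", "MAPE", "SSE", "n"}

    def test_rows_per_method_seed_pair(self, default_series):
        table = forecaster.compare_methods(
            default_series, (2012, 11), methods=["bpann", "pso_bpann"],
            seeds=[0, 1], **SMALL
        )
        assert len(table) == 4

    def test_no_methods_rejected(self, default_series):
        with pytest.raises(InvalidInputError):
            forecaster.compare_methods(default_series, (2012, 11), methods=[])
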