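"""Quantile maps, training table, bridge regressor, per-cell prediction."""

import numpy as np
import pandas as pd
import pytest

from citequant.bridge import (
    DEFAULT_QUANTILE_GRID,
    FEATURE_ADT,
    TARGET,
    build_quantile_map,
    build_training_table,
    leave_one_antigen_out,
    load_model,
    predict_cell_abc,
    save_model,
    train_model,
)
from citequant.preprocess import QC_METRIC_NAMES


def _qc(sample_ids, seed=0):
    rng = np.random.default_rng(seed)
    return {
        sid: pd.Series(rng.uniform(10, 90, len(QC_METRIC_NAMES)), index=QC_METRIC_NAMES)
        for sid in sample_ids
    }


def _training_table(n_rows=500, seed=0, slope=1.0, noise=0.0, constant_qc=False):
    """Table whose target is (optionally noisy) linear in the ADT feature."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({FEATURE_ADT: rng.uniform(-2, 2, n_rows)})
    for name in QC_METRIC_NAMES:
        table[name] = 50.0 if constant_qc else rng.uniform(0, 100, n_rows)
    table[TARGET] = 3.0 + slope * table[FEATURE_ADT] + rng.normal(0, noise, n_rows)
    table["sample_id"] = "s1"
    table["antigen"] = "CD33"
    return table


class TestQuantileMap:
    def test_identity_distributions_give_identity_map(self):
        rng = np.random.default_rng(0)
        log_abc = rng.normal(3, 0.4, 5000)
        qm = build_quantile_map(10.0**log_abc, log_abc)
        np.testing.assert_allclose(qm.adt_quantiles, qm.abc_log10_quantiles, atol=1e-9)

    def test_monotone_transform_commutes(self):
        rng = np.random.default_rng(1)
        # n chosen so every 5% grid level is an exact order statistic,
        # where quantiles commute with monotone transforms exactly
        adt = rng.lognormal(1, 0.5, 2001)
        qm = build_quantile_map(100.0 * adt, adt)
        np.testing.assert_allclose(
            qm.abc_log10_quantiles,
            np.log10(100.0 * np.asarray(qm.adt_quantiles)),
            atol=1e-9,
        )

    def test_quantile_matches_order_statistic_oracle(self):
        values = np.arange(1.0, 101.0)
        qm = build_quantile_map(values, values, grid=(0.25,))
        # linear interpolation between order statistics: h = (n-1)q = 24.75,
        # i.e. 3/4 of the way from the 25th to the 26th order statistic
        assert qm.adt_quantiles[0] == pytest.approx(1.0 + 24.75)
        log_oracle = np.log10(25.0) + 0.75 * (np.log10(26.0) - np.log10(25.0))
        assert qm.abc_log10_quantiles[0] == pytest.approx(log_oracle, abs=1e-12)

    def test_default_grid_is_19_levels(self):
        assert len(DEFAULT_QUANTILE_GRID) == 19
        assert DEFAULT_QUANTILE_GRID[0] == pytest.approx(0.05)
        assert DEFAULT_QUANTILE_GRID[-1] == pytest.approx(0.95)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_quantile_map([], [1.0])
        with pytest.raises(ValueError):
            build_quantile_map([1.0], [])

    def test_small_sample_warns_but_interpolates(self):
        with pytest.warns(UserWarning, match="fewer observations"):
            qm = build_quantile_map([10.0, 100.0], [0.0, 1.0])
        assert len(qm.adt_quantiles) == 19

    def test_monotone_outputs_enforced(self):
        rng = np.random.default_rng(2)
        qm = build_quantile_map(rng.lognormal(3, 1, 500), rng.normal(0, 1, 500))
        assert (np.diff(qm.adt_quantiles) >= 0).all()
        assert (np.diff(qm.abc_log10_quantiles) >= 0).all()


class TestTrainingTable:
    def _maps(self, sample_ids, antigens, seed=0):
        rng = np.random.default_rng(seed)
        return [
            build_quantile_map(
                rng.lognormal(3, 0.5, 400), rng.normal(0, 1, 400),
                sample_id=sid, antigen=a,
            )
            for sid in sample_ids
            for a in antigens
        ]

    def test_row_count_is_product(self):
        maps = self._maps(["s1", "s2"], ["a", "b", "c", "d"])
        table = build_training_table(maps, _qc(["s1", "s2"]))
        assert len(table) == 2 * 4 * 19

    def test_missing_qc_names_sample(self):
        maps = self._maps(["s1", "s2"], ["a"])
        with pytest.raises(KeyError, match="s2"):
            build_training_table(maps, _qc(["s1"]))

    def test_csv_round_trip(self, tmp_path):
        maps = self._maps(["s1"], ["a", "b"])
        table = build_training_table(maps, _qc(["s1"]))
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, atol=1e-12)


class TestTrainModel:
    def test_linear_signal_recovered(self):
        # the QC metrics carry no information here (constant, as within one
        # sample); held-out error must collapse to interpolation error
        table = _training_table(n_rows=500, noise=0.0, constant_qc=True)
        model = train_model(table, seed=0, cv_repeats=2)
        target_sd = table[TARGET].std()
        assert model.cv_rmse_mean_ <= 0.1 * target_sd

    def test_constant_target_predicts_constant(self):
        table = _training_table(n_rows=100)
        table[TARGET] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            model = train_model(table, seed=0, cv_repeats=0)
        features = [FEATURE_ADT, *QC_METRIC_NAMES]
        pred = model.predict(table[features])
        np.testing.assert_allclose(pred, 2.5)

    def test_seed_determinism(self):
        table = _training_table(n_rows=200, noise=0.2)
        features = [FEATURE_ADT, *QC_METRIC_NAMES]
        a = train_model(table, seed=7, cv_repeats=2)
        b = train_model(table, seed=7, cv_repeats=2)
        assert a.cv_rmse_mean_ == b.cv_rmse_mean_
        np.testing.assert_array_equal(
            a.predict(table[features]), b.predict(table[features])
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            train_model(_training_table(n_rows=10), seed=0)


class TestPredictCellAbc:
    def test_identity_relationship_recovered(self, qc_series):
        table = _training_table(n_rows=600, noise=0.05)
        model = train_model(table, seed=1, cv_repeats=2)
        rng = np.random.default_rng(4)
        adt = pd.DataFrame({"CD33": rng.uniform(-1.5, 1.5, 50)})
        qc = pd.Series(
            {name: 50.0 for name in QC_METRIC_NAMES}
        )
        est = predict_cell_abc(model, adt, qc)
        pred_log10 = np.log10(est["CD33"])
        expected = 3.0 + adt["CD33"]
        tol = max(3 * model.cv_rmse_mean_, 0.15)
        assert np.median(np.abs(pred_log10 - expected)) <= tol

    def test_output_strictly_positive(self, qc_series):
        table = _training_table(n_rows=200, noise=0.3)
        model = train_model(table, seed=2, cv_repeats=0)
        adt = pd.DataFrame({"CD33": [-10.0, 0.0, 10.0]})
        est = predict_cell_abc(model, adt, qc_series)
        assert (est.to_numpy() > 0).all()

    def test_clipping_bounds_respected(self, qc_series):
        table = _training_table(n_rows=200, noise=0.0)
        model = train_model(table, seed=3, cv_repeats=0)
        adt = pd.DataFrame({"CD33": [-100.0, 100.0]})
        est = predict_cell_abc(model, adt, qc_series, clip_margin=0.5)
        log_est = np.log10(est["CD33"])
        assert log_est.min() >= model.target_min_ - 0.5 - 1e-9
        assert log_est.max() <= model.target_max_ + 0.5 + 1e-9

    def test_missing_antigen_rejected(self, qc_series):
        table = _training_table(n_rows=100, noise=0.1)
        model = train_model(table, seed=4, cv_repeats=0)
        adt = pd.DataFrame({"CD33": [0.0]})
        with pytest.raises(KeyError, match="CD99"):
            predict_cell_abc(model, adt, qc_series, antigens=["CD99"])


class TestModelSerialization:
    def test_round_trip(self, tmp_path):
        table = _training_table(n_rows=120, noise=0.1)
        model = train_model(table, seed=5, cv_repeats=0)
        path = tmp_path / "model.pkl"
        save_model(model, path)
        loaded = load_model(path)
        features = [FEATURE_ADT, *QC_METRIC_NAMES]
        np.testing.assert_array_equal(
            loaded.predict(table[features]), model.predict(table[features])
        )


class TestLeaveOneAntigenOut:
    @pytest.fixture(scope="class")
    def loao_inputs(self):
        """Shared ADT<->ABC relationship across 4 antigens and 6 samples."""
        rng = np.random.default_rng(8)
        antigens = ["CD33", "CLL-1", "CD123", "ADGRE2"]
        sample_ids = [f"s{i}" for i in range(6)]
        # constant QC: no artifact variation in this noise-free setting
        qc = {
            sid: pd.Series(50.0, index=QC_METRIC_NAMES) for sid in sample_ids
        }
        maps, matrices, flow_mean = [], {}, {}
        for sid in sample_ids:
            cols = {}
            for antigen in antigens:
                mu = rng.uniform(2.5, 4.0)
                log_abc = rng.normal(mu, 0.25, 800)
                adt = log_abc - 3.0  # shared noiseless monotone relationship
                maps.append(
                    build_quantile_map(10.0**log_abc, adt, sample_id=sid, antigen=antigen)
                )
                cols[antigen] = adt
                flow_mean[(sid, antigen)] = float(np.mean(10.0**log_abc))
            matrices[sid] = pd.DataFrame(cols)
        return maps, qc, matrices, flow_mean

    def test_one_iteration_per_bridge_antigen(self, loao_inputs):
        maps, qc, matrices, flow_mean = loao_inputs
        report = leave_one_antigen_out(maps, qc, matrices, flow_mean, seed=0)
        assert sorted(report["excluded_antigen"]) == ["ADGRE2", "CD123", "CD33", "CLL-1"]

    def test_excluded_antigen_absent_from_training(self, loao_inputs):
        maps, qc, matrices, flow_mean = loao_inputs
        report = leave_one_antigen_out(maps, qc, matrices, flow_mean, seed=0)
        for excluded, trained_on in report.attrs["training_antigens"].items():
            assert excluded not in trained_on
            assert len(trained_on) == 3

    def test_shared_relationship_gives_high_concordance(self, loao_inputs):
        maps, qc, matrices, flow_mean = loao_inputs
        report = leave_one_antigen_out(maps, qc, matrices, flow_mean, seed=0)
        assert (report["spearman"] >= 0.9).all()

    def test_fewer_than_two_antigens_rejected(self, loao_inputs):
        maps, qc, matrices, flow_mean = loao_inputs
        only = [qm for qm in maps if qm.antigen == "CD33"]
        with pytest.raises(ValueError, match="2 bridge antigens"):
            leave_one_antigen_out(only, qc, matrices, flow_mean)
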