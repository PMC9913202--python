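"""Pipeline orchestration, correlation analysis, metrics and harnesses."""

import numpy as np
import pytest

import stlcast as sc
from stlcast.forecaster import ForecastComponents, full_sweep_grid
from stlcast.residual_model import InformerConfig


class TestForecastComponents:
    def test_total_is_sum_of_parts(self):
        c = ForecastComponents(np.array([1.0]), np.array([2.0]), np.array([0.5]))
        assert c.total[0] == 3.5

    def test_zero_trend_and_residual_leaves_seasonal(self, rng):
        seas = rng.normal(size=7)
        c = ForecastComponents(np.zeros(7), seas, np.zeros(7))
        np.testing.assert_array_equal(c.total, seas)

    def test_mismatched_horizons_error(self):
        with pytest.raises(ValueError):
            ForecastComponents(np.zeros(3), np.zeros(4), np.zeros(3))


class TestPipeline:
    def test_structure_after_fit(self, tiny_pipeline):
        p = tiny_pipeline
        assert len(p.decomps) == 3
        assert p.trend_model is not None and p.residual_model is not None

    def test_additivity_holds_on_every_forecast(self, tiny_pipeline):
        p = tiny_pipeline
        for end in (24, 100, 250, p.series.n_samples):
            for physical in (False, True):
                c = p.predict(end, physical=physical)
                np.testing.assert_array_equal(
                    c.total, c.trend_pred + c.seasonal_proj + c.residual_pred
                )

    def test_physical_and_normalized_forecasts_agree(self, tiny_pipeline):
        p = tiny_pipeline
        c_norm = p.predict(200)
        c_phys = p.predict(200, physical=True)
        rng_ = (p.normalizer.x_max - p.normalizer.x_min)[p._tgt]
        off = p.normalizer.x_min[p._tgt]
        np.testing.assert_allclose(c_phys.total, c_norm.total * rng_ + off, atol=1e-10)

    def test_single_channel_ablation_mode(self, small_series):
        cfg = sc.PipelineConfig(
            residual=InformerConfig.reduced(epochs=1, steps_per_epoch=2),
            trend=sc.TrendModelConfig(epochs=1), train_stride=16,
        )
        p = sc.fit_pipeline(small_series, "temperature", cfg, seed=0,
                            input_channels=["temperature"])
        c = p.predict(300)
        assert c.total.shape == (7,)

    def test_unknown_target_errors(self, small_series):
        with pytest.raises(ValueError):
            sc.fit_pipeline(small_series, "pressure", sc.PipelineConfig(), seed=0)

    def test_refit_same_seed_identical_forecasts(self, small_series):
        cfg = sc.PipelineConfig(
            residual=InformerConfig.reduced(epochs=1, steps_per_epoch=2),
            trend=sc.TrendModelConfig(epochs=1), train_stride=16,
        )
        a = sc.fit_pipeline(small_series, "temperature", cfg, seed=5).predict(300)
        b = sc.fit_pipeline(small_series, "temperature", cfg, seed=5).predict(300)
        np.testing.assert_array_equal(a.total, b.total)

    def test_horizon_beyond_configured_errors(self, tiny_pipeline):
        with pytest.raises(ValueError):
            tiny_pipeline.predict(200, pred_len=99)

    def test_checkpoint_round_trip(self, tiny_pipeline, tmp_path):
        path = tmp_path / "pipe.npz"
        tiny_pipeline.save(path)
        back = sc.Pipeline.load(path)
        for end in (50, 200, 400):
            a = tiny_pipeline.predict(end, physical=True)
            b = back.predict(end, physical=True)
            np.testing.assert_allclose(a.total, b.total, atol=1e-12)


class TestPearson:
    def test_perfect_anticorrelation(self, rng):
        x = rng.normal(size=100)
        C = sc.pearson_matrix(np.column_stack([x, -x]))
        assert C[0, 1] == pytest.approx(-1.0)

    def test_self_correlation_and_symmetry(self, rng):
        X = rng.normal(size=(200, 3))
        C = sc.pearson_matrix(X)
        np.testing.assert_allclose(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T)
        assert np.abs(C).max() <= 1.0 + 1e-12

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            sc.pearson_matrix(np.column_stack([np.ones(10), np.arange(10.0)]))

    def test_generator_hits_published_targets(self):
        s = sc.generate(sc.SyntheticSpec(n_samples=4320, seed=17))
        C = sc.pearson_matrix(s)
        T = np.array(sc.synthetic.TABLE_TARGETS["corr"])
        assert np.abs(C - T).max() < 0.1


class TestRelativeAbsChange:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(-0.5149, -0.6424, 24.76), (0.6505, 0.7198, 10.65)],
    )
    def test_published_residual_correlation_increases(self, before, after, expected):
        assert sc.relative_abs_change(before, after) == pytest.approx(expected, abs=0.005)

    def test_no_change_is_zero(self):
        assert sc.relative_abs_change(0.7, 0.7) == 0.0

    def test_zero_before_errors(self):
        with pytest.raises(ValueError):
            sc.relative_abs_change(0.0, 0.5)


class TestMetrics:
    def test_perfect_forecast(self):
        m = sc.compute_metrics(np.arange(5.0), np.arange(5.0))
        assert m == {"MAE": 0.0, "MSE": 0.0, "RMSE": 0.0}

    def test_unit_errors(self):
        m = sc.compute_metrics(np.zeros(2), np.array([1.0, -1.0]))
        assert (m["MAE"], m["MSE"], m["RMSE"]) == (1.0, 1.0, 1.0)

    def test_hand_worked_example(self):
        m = sc.compute_metrics(np.zeros(2), np.array([3.0, 4.0]))
        assert m["MAE"] == pytest.approx(3.5)
        assert m["MSE"] == pytest.approx(12.5)
        assert m["RMSE"] == pytest.approx(3.53553, abs=1e-5)

    def test_rmse_is_root_of_mse(self, rng):
        m = sc.compute_metrics(rng.normal(size=50), rng.normal(size=50))
        assert m["RMSE"] == pytest.approx(np.sqrt(m["MSE"]), abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            sc.compute_metrics(np.zeros(3), np.zeros(4))


class TestHarnesses:
    def test_full_grid_has_30_combinations(self):
        grid = full_sweep_grid()
        assert len(grid) == 30
        assert (24, 12, 7) in grid and (24, 0, 7) in grid

    def test_sweep_single_cell_and_determinism(self, small_series):
        cfg = sc.PipelineConfig(residual=InformerConfig.reduced(epochs=1, steps_per_epoch=2),
                                train_stride=16)
        a = sc.run_window_sweep(small_series, [(24, 12, 7)], cfg, seed=0,
                                n_train=360, eval_stride=8)
        b = sc.run_window_sweep(small_series, [(24, 12, 7)], cfg, seed=0,
                                n_train=360, eval_stride=8)
        assert len(a) == 1
        assert a["MSE"][0] == b["MSE"][0]

    def test_sweep_skips_invalid_combinations(self, small_series):
        cfg = sc.PipelineConfig(residual=InformerConfig.reduced(epochs=1, steps_per_epoch=2),
                                train_stride=16)
        df = sc.run_window_sweep(small_series, [(8, 12, 7), (24, 12, 7)], cfg,
                                 seed=0, n_train=360, eval_stride=8)
        assert len(df) == 1  # label_len > seq_len row dropped

    def test_ablation_table_shape_and_zero_self_improvement(self, small_series):
        cfg = sc.PipelineConfig(residual=InformerConfig.reduced(epochs=1, steps_per_epoch=2),
                                trend=sc.TrendModelConfig(epochs=1), train_stride=16)
        subsets = [["temperature"], ["temperature", "humidity"],
                   ["temperature", "humidity", "co2"]]
        df = sc.run_ablation(small_series, "temperature", subsets, cfg, seed=0,
                             n_train=400, eval_stride=8)
        assert (df["kind"] == "metrics").sum() == 3
        assert (df["kind"] == "improvement_pct").sum() == 2

        same = sc.run_ablation(small_series, "temperature",
                               [["temperature"], ["temperature"]], cfg, seed=0,
                               n_train=400, eval_stride=8)
        imp = same[same["kind"] == "improvement_pct"].iloc[0]
        assert imp["MSE"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_subset_errors(self, small_series):
        with pytest.raises(ValueError):
            sc.run_ablation(small_series, "temperature", [[]], sc.PipelineConfig())

    def test_comparison_table_shape(self, small_series):
        cfg = sc.PipelineConfig(residual=InformerConfig.reduced(epochs=1, steps_per_epoch=2),
                                trend=sc.TrendModelConfig(epochs=1), train_stride=16)
        df = sc.run_model_comparison(small_series, "temperature", cfg, seed=0,
                                     n_train=400, models=("Informer", "SVR"),
                                     eval_stride=8)
        assert set(df["model"]) == {"Informer", "SVR"}
        assert {"MAE", "MSE", "RMSE"} <= set(df.columns)
        assert (df[["MAE", "MSE", "RMSE"]] >= 0).all().all()
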