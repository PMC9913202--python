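"""Three-stage forecasting pipeline and the analysis/experiment harnesses.

The pipeline: decompose every input channel with STL, forecast the trend with
the LSTM and the residual with the Informer-style network, tile the seasonal
cycle forward, and sum the three parts to obtain the forecast —
``I_p = I_t_p + I_s + I_r_p`` — in multi-input/single-output mode.

Also here: Pearson correlation analysis of raw channels and of their STL
residuals (the decomposition strengthens the cross-channel coupling, which
is the reason the residual model is multivariate), MAE/MSE/RMSE scoring, a
(seq_len, label_len, pred_len) sweep harness, a model-comparison harness
with direct-Informer / SVR / XGBoost baselines, and an input-cardinality
ablation harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    NormalizationParams,
    RegularSeries,
    WindowBatch,
    fit_normalizer,
    impute_missing,
    make_windows,
    normalize,
    time_features,
)
from .decomposition import (
    DEFAULT_PERIOD,
    DEFAULT_SEASONAL_SMOOTHER,
    DecompositionResult,
    project_seasonal,
    stl_decompose,
)
from .residual_model import InformerConfig, InformerModel, train_residual
from .trend_model import TrendModel, TrendModelConfig, predict_trend, train_trend

logger = logging.getLogger("stlcast")

__all__ = [
    "PipelineConfig",
    "ForecastComponents",
    "Pipeline",
    "fit_pipeline",
    "pearson_matrix",
    "residual_pearson_matrix",
    "relative_abs_change",
    "compute_metrics",
    "evaluate_pipeline",
    "mean_predictor_mse",
    "train_direct_informer",
    "evaluate_direct_informer",
    "run_window_sweep",
    "run_model_comparison",
    "run_ablation",
]


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end settings for the decomposition pipeline.

    Windowing follows the best-performing setting of the sequence-length
    sweep (seq_len 24 = 4 h, label_len 12, pred_len 7 = 70 min at 10-minute
    sampling).  ``residual`` defaults to the reduced desk-scale Informer
    profile; pass ``InformerConfig()`` for the full-size one.
    """

    seq_len: int = 24
    label_len: int = 12
    pred_len: int = 7
    period: int = DEFAULT_PERIOD
    seasonal_smoother: int = DEFAULT_SEASONAL_SMOOTHER
    robust: bool = True
    train_stride: int = 1
    trend: TrendModelConfig | None = None
    residual: InformerConfig | None = None

    def __post_init__(self):
        if self.label_len > self.seq_len:
            raise ValueError("label_len must not exceed seq_len")


@dataclass
class ForecastComponents:
    """One multi-step forecast split into its three additive parts.

    ``total`` is exactly ``trend_pred + seasonal_proj + residual_pred``
    (computed once, elementwise); on the physical scale the min–max offset is
    carried by the trend part so the additive identity survives
    denormalization.
    """

    trend_pred: np.ndarray
    seasonal_proj: np.ndarray
    residual_pred: np.ndarray
    total: np.ndarray = field(init=False)

    def __post_init__(self):
        if not (len(self.trend_pred) == len(self.seasonal_proj) == len(self.residual_pred)):
            raise ValueError("component horizons disagree")
        self.total = self.trend_pred + self.seasonal_proj + self.residual_pred


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

class Pipeline:
    """Fitted decomposition pipeline over one series history.

    The STL decomposition is computed once on the full available history (a
    per-window STL at seq_len 24 ≪ period 144 would be unstable); at predict
    time the trend/residual models read the component values of the encoder
    window and the seasonal cycle is tiled past the window end.
    """

    def __init__(self, cfg: PipelineConfig, channel_names: list[str],
                 input_channels: list[str], target_channel: str, seed: int):
        self.cfg = cfg
        self.channel_names = channel_names
        self.input_channels = input_channels
        self.target_channel = target_channel
        self.seed = seed
        self.normalizer: NormalizationParams | None = None
        self.decomps: list[DecompositionResult] = []
        self.trend_model: TrendModel | None = None
        self.residual_model: InformerModel | None = None
        self.trend_cfg: TrendModelConfig | None = None
        self.residual_cfg: InformerConfig | None = None
        self.series: RegularSeries | None = None
        self.n_train: int | None = None

    # -- component matrices (normalized scale) ------------------------------
    @property
    def _tgt(self) -> int:
        return self.channel_names.index(self.target_channel)

    @property
    def _in_idx(self) -> list[int]:
        return [self.channel_names.index(c) for c in self.input_channels]

    def trend_matrix(self) -> np.ndarray:
        return np.column_stack([d.trend for d in self.decomps])

    def residual_matrix(self) -> np.ndarray:
        return np.column_stack([d.residual for d in self.decomps])

    def fit(self, series: RegularSeries, n_train: int | None = None) -> "Pipeline":
        cfg = self.cfg
        if self.target_channel not in series.channel_names:
            raise ValueError(f"unknown target channel {self.target_channel!r}")
        series = impute_missing(series)
        self.series = series
        n = series.n_samples
        self.n_train = n if n_train is None else n_train
        self.normalizer = fit_normalizer(series, slice(0, self.n_train))
        norm_vals = normalize(series.values, self.normalizer)
        self.decomps = [
            stl_decompose(norm_vals[:, c], period=cfg.period, robust=cfg.robust,
                          seasonal_smoother=cfg.seasonal_smoother)
            for c in range(series.n_channels)
        ]
        trend_mat = self.trend_matrix()
        resid_mat = self.residual_matrix()

        # training windows live entirely inside the training span
        train_ts = series.timestamps[: self.n_train]
        sub = RegularSeries(train_ts, norm_vals[: self.n_train],
                            list(series.channel_names))
        tgt = self._tgt
        in_idx = self._in_idx

        def windows_from(mat: np.ndarray) -> WindowBatch:
            wb = make_windows(sub, cfg.seq_len, cfg.label_len, cfg.pred_len,
                              self.target_channel, stride=cfg.train_stride,
                              values=mat[: self.n_train])
            wb.enc_x = wb.enc_x[:, :, in_idx]
            wb.dec_x = wb.dec_x[:, :, in_idx]
            return wb

        trend_wb = windows_from(trend_mat)
        resid_wb = windows_from(resid_mat)

        # the LSTM forecasts the trend *increment* from the window-end value:
        # the trend varies slowly, so increments start near the model's
        # near-zero untrained output and only the local slope must be learnt
        starts = np.arange(0, self.n_train - cfg.seq_len - cfg.pred_len + 1,
                           cfg.train_stride)
        anchors = trend_mat[starts + cfg.seq_len - 1, tgt]
        tcfg = self.cfg.trend or TrendModelConfig(pred_len=cfg.pred_len)
        tcfg.input_size = len(in_idx)
        tcfg.pred_len = cfg.pred_len
        self.trend_cfg = tcfg
        self.trend_model = train_trend(
            trend_wb, tcfg, seed=self.seed,
            targets=trend_wb.target - anchors[:, None])

        rcfg = self.cfg.residual or InformerConfig.reduced()
        rcfg.input_size = len(in_idx)
        rcfg.pred_len = cfg.pred_len
        self.residual_cfg = rcfg
        self.residual_model = train_residual(resid_wb, rcfg, seed=self.seed)
        return self

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        """Write the fitted pipeline (weights, configs, normalizer, series
        history and decomposition) into a single ``.npz`` archive."""
        import dataclasses
        import json

        if self.trend_model is None:
            raise RuntimeError("pipeline is not fitted")
        meta = {
            "channel_names": self.channel_names,
            "input_channels": self.input_channels,
            "target_channel": self.target_channel,
            "seed": self.seed,
            "n_train": self.n_train,
            "cfg": {k: v for k, v in dataclasses.asdict(self.cfg).items()
                    if k not in ("trend", "residual")},
            "trend_cfg": dataclasses.asdict(self.trend_cfg),
            "residual_cfg": dataclasses.asdict(self.residual_cfg),
        }
        arrays = {
            "timestamps": self.series.timestamps.asi8,
            "values": self.series.values,
            "missing_mask": self.series.missing_mask,
            "x_min": self.normalizer.x_min,
            "x_max": self.normalizer.x_max,
            "trend_mat": self.trend_matrix(),
            "seasonal_mat": np.column_stack([d.seasonal for d in self.decomps]),
            "residual_mat": self.residual_matrix(),
        }
        for i, p in enumerate(self.trend_model.parameters()):
            arrays[f"trend_p{i}"] = p.data
        for i, p in enumerate(self.residual_model.parameters()):
            arrays[f"resid_p{i}"] = p.data
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Pipeline":
        import json

        from .trend_model import TrendModel

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cfg = PipelineConfig(
                **meta["cfg"],
                trend=TrendModelConfig(**meta["trend_cfg"]),
                residual=InformerConfig(**meta["residual_cfg"]),
            )
            pipe = cls(cfg, meta["channel_names"], meta["input_channels"],
                       meta["target_channel"], meta["seed"])
            pipe.n_train = meta["n_train"]
            pipe.trend_cfg = cfg.trend
            pipe.residual_cfg = cfg.residual
            pipe.series = RegularSeries(
                pd.DatetimeIndex(z["timestamps"].view("datetime64[ns]")),
                z["values"], meta["channel_names"], z["missing_mask"])
            pipe.normalizer = NormalizationParams(z["x_min"], z["x_max"])
            pipe.decomps = [
                DecompositionResult(z["trend_mat"][:, c], z["seasonal_mat"][:, c],
                                    z["residual_mat"][:, c], cfg.period)
                for c in range(len(meta["channel_names"]))
            ]
            pipe.trend_model = TrendModel(cfg.trend, seed=meta["seed"])
            for i, p in enumerate(pipe.trend_model.parameters()):
                p.data = z[f"trend_p{i}"]
            from .residual_model import InformerModel

            pipe.residual_model = InformerModel(cfg.residual, seed=meta["seed"])
            for i, p in enumerate(pipe.residual_model.parameters()):
                p.data = z[f"resid_p{i}"]
        return pipe

    # -- prediction ----------------------------------------------------------
    def predict(self, window_end: int, pred_len: int | None = None,
                physical: bool = False) -> ForecastComponents:
        """Forecast the ``pred_len`` steps after sample index ``window_end``.

        The encoder window is ``[window_end − seq_len, window_end)``.  With
        ``physical=True`` the parts are rescaled to the target's physical
        units (the min–max offset rides on the trend part).
        """
        cfg = self.cfg
        p = cfg.pred_len if pred_len is None else pred_len
        if p > cfg.pred_len:
            raise ValueError("horizon beyond the configured pred_len")
        if not cfg.seq_len <= window_end <= self.series.n_samples:
            raise ValueError("window does not fit in the series")
        s, l = cfg.seq_len, cfg.label_len
        i0 = window_end - s
        in_idx = self._in_idx

        trend_mat = self.trend_matrix()
        trend_win = trend_mat[i0:window_end][:, in_idx]
        anchor = trend_mat[window_end - 1, self._tgt]
        trend_pred = anchor + predict_trend(self.trend_model, trend_win)[:p]

        seasonal = project_seasonal(self.decomps[self._tgt], p, anchor=window_end)

        resid_mat = self.residual_matrix()[:, in_idx]
        feats = time_features(self.series.timestamps)
        enc_x = resid_mat[i0:window_end][None]
        dec_x = np.zeros((1, l + cfg.pred_len, len(in_idx)))
        if l:
            dec_x[0, :l] = resid_mat[window_end - l : window_end]
        enc_t = feats[i0:window_end][None]
        # decoder covers [window_end − l, window_end + pred_len)
        dec_rows = np.arange(window_end - l, window_end + cfg.pred_len)
        dec_t = _extended_time_features(self.series, dec_rows)[None]
        resid_pred = self.residual_model.forward(enc_x, enc_t, dec_x, dec_t).data[0][:p]

        comp = ForecastComponents(trend_pred=trend_pred, seasonal_proj=seasonal,
                                  residual_pred=resid_pred)
        if physical:
            rng_ = (self.normalizer.x_max - self.normalizer.x_min)[self._tgt]
            off = self.normalizer.x_min[self._tgt]
            comp = ForecastComponents(
                trend_pred=comp.trend_pred * rng_ + off,
                seasonal_proj=comp.seasonal_proj * rng_,
                residual_pred=comp.residual_pred * rng_,
            )
        return comp

    def true_future(self, window_end: int, pred_len: int | None = None) -> np.ndarray:
        """Normalized true target values for the horizon after ``window_end``."""
        p = self.cfg.pred_len if pred_len is None else pred_len
        vals = normalize(self.series.values, self.normalizer)
        return vals[window_end : window_end + p, self._tgt]


def _extended_time_features(series: RegularSeries, rows: np.ndarray) -> np.ndarray:
    """Time features for row indices possibly past the series end."""
    step = series.timestamps[1] - series.timestamps[0]
    ts = series.timestamps[0] + step * rows
    return time_features(pd.DatetimeIndex(ts))


def fit_pipeline(train_series: RegularSeries, target_channel: str,
                 cfg: PipelineConfig | None = None, seed: int = 0,
                 input_channels: list[str] | None = None,
                 n_train: int | None = None) -> Pipeline:
    """Fit the three-stage pipeline on a series history.

    ``input_channels`` restricts the model inputs (ablation mode); the
    decomposition always covers every channel of ``train_series`` so the
    target's seasonal and trend remain available.  With ``n_train`` the
    normalizer and the training windows use only the first ``n_train``
    samples while the decomposition covers the full history (so held-out
    windows can be scored afterwards).
    """
    cfg = cfg or PipelineConfig()
    input_channels = input_channels or list(train_series.channel_names)
    pipe = Pipeline(cfg, list(train_series.channel_names), list(input_channels),
                    target_channel, seed)
    return pipe.fit(train_series, n_train=n_train)


# ---------------------------------------------------------------------------
# correlation analysis
# ---------------------------------------------------------------------------

def pearson_matrix(values: np.ndarray | RegularSeries) -> np.ndarray:
    """Pearson correlation matrix of the channels (symmetric, unit diagonal)."""
    x = values.values if isinstance(values, RegularSeries) else np.asarray(values, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (x.std(axis=0) == 0).any():
        raise ValueError("zero-variance channel")
    return np.corrcoef(x, rowvar=False)


def residual_pearson_matrix(series: RegularSeries, period: int = DEFAULT_PERIOD,
                            **stl_kw) -> np.ndarray:
    """Pearson correlation of the channels' STL residuals."""
    resid = np.column_stack([
        stl_decompose(series.values[:, c], period=period, **stl_kw).residual
        for c in range(series.n_channels)
    ])
    return pearson_matrix(resid)


def relative_abs_change(r_before: float, r_after: float) -> float:
    """Percent change in correlation magnitude: 100·(|after| − |before|)/|before|."""
    if r_before == 0:
        raise ValueError("r_before must be nonzero")
    return 100.0 * (abs(r_after) - abs(r_before)) / abs(r_before)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """MAE, MSE and RMSE of a forecast (RMSE = √MSE by construction)."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    e = y_pred - y_true
    mse = float(np.mean(e * e))
    return {"MAE": float(np.mean(np.abs(e))), "MSE": mse, "RMSE": float(np.sqrt(mse))}


def _test_window_ends(pipe_or_n, seq_len: int, pred_len: int, test_start: int, n: int,
                      stride: int = 1) -> np.ndarray:
    first = max(test_start, seq_len)
    return np.arange(first, n - pred_len + 1, stride)


def evaluate_pipeline(pipe: Pipeline, test_start: int | None = None,
                      stride: int = 1) -> dict[str, float]:
    """Walk the held-out span with stride-1 windows and average the metrics.

    Returns normalized-scale MAE/MSE/RMSE plus their physical-unit
    counterparts (suffix ``_phys``); errors scale by the target's min–max
    range, so ``_phys = normalized · range`` for MAE/RMSE.
    """
    cfg = pipe.cfg
    n = pipe.series.n_samples
    test_start = pipe.n_train if test_start is None else test_start
    ends = _test_window_ends(pipe, cfg.seq_len, cfg.pred_len, test_start, n, stride)
    if len(ends) == 0:
        raise ValueError("no test windows fit")
    preds = np.array([pipe.predict(int(e)).total for e in ends])
    truth = np.array([pipe.true_future(int(e)) for e in ends])
    m = compute_metrics(truth, preds)
    rng_ = float((pipe.normalizer.x_max - pipe.normalizer.x_min)[pipe._tgt])
    m.update({"MAE_phys": m["MAE"] * rng_, "MSE_phys": m["MSE"] * rng_**2,
              "RMSE_phys": m["RMSE"] * rng_})
    return m


def mean_predictor_mse(pipe: Pipeline, test_start: int | None = None,
                       stride: int = 1) -> float:
    """Normalized MSE of the constant train-mean forecaster on the same windows."""
    cfg = pipe.cfg
    n = pipe.series.n_samples
    test_start = pipe.n_train if test_start is None else test_start
    norm_vals = normalize(pipe.series.values, pipe.normalizer)
    mu = norm_vals[: pipe.n_train, pipe._tgt].mean()
    ends = _test_window_ends(pipe, cfg.seq_len, cfg.pred_len, test_start, n, stride)
    truth = np.concatenate([norm_vals[e : e + cfg.pred_len, pipe._tgt] for e in ends])
    return float(np.mean((truth - mu) ** 2))


# ---------------------------------------------------------------------------
# direct (non-decomposed) Informer baseline
# ---------------------------------------------------------------------------

def _normalized_windows(series: RegularSeries, params: NormalizationParams,
                        seq_len: int, label_len: int, pred_len: int,
                        target_channel: str, stride: int = 1,
                        lo: int = 0, hi: int | None = None) -> WindowBatch:
    hi = series.n_samples if hi is None else hi
    sub = RegularSeries(series.timestamps[lo:hi],
                        normalize(series.values[lo:hi], params),
                        list(series.channel_names))
    return make_windows(sub, seq_len, label_len, pred_len, target_channel, stride=stride)


def train_direct_informer(series: RegularSeries, target_channel: str,
                          cfg: PipelineConfig, seed: int = 0,
                          n_train: int | None = None
                          ) -> tuple[InformerModel, NormalizationParams]:
    """Informer trained on the raw (undecomposed) normalized series."""
    series = impute_missing(series)
    n_train = series.n_samples if n_train is None else n_train
    params = fit_normalizer(series, slice(0, n_train))
    wb = _normalized_windows(series, params, cfg.seq_len, cfg.label_len,
                             cfg.pred_len, target_channel,
                             stride=cfg.train_stride, hi=n_train)
    rcfg = cfg.residual or InformerConfig.reduced()
    rcfg.input_size = series.n_channels
    rcfg.pred_len = cfg.pred_len
    model = train_residual(wb, rcfg, seed=seed)
    return model, params


def evaluate_direct_informer(model: InformerModel, params: NormalizationParams,
                             series: RegularSeries, target_channel: str,
                             cfg: PipelineConfig, test_start: int,
                             stride: int = 1) -> dict[str, float]:
    series = impute_missing(series)
    lo = max(0, test_start - cfg.seq_len)
    wb = _normalized_windows(series, params, cfg.seq_len, cfg.label_len,
                             cfg.pred_len, target_channel, stride=stride, lo=lo)
    preds = model.predict(wb)
    return compute_metrics(wb.target, preds)


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

def run_window_sweep(series: RegularSeries, grid, cfg: PipelineConfig | None = None,
                     seed: int = 0, n_train: int | None = None,
                     target_channel: str | None = None,
                     eval_stride: int = 1) -> pd.DataFrame:
    """MSE of the direct Informer over a (seq_len, label_len, pred_len) grid.

    Mirrors the sequence-length selection experiment (the sweep is over the
    attention model alone, CO2 as output); invalid combinations are skipped
    with a logged warning.  Returns one row per valid combination.
    """
    cfg = cfg or PipelineConfig()
    target_channel = target_channel or series.channel_names[-1]
    n_train = n_train or int(series.n_samples * 8 / 9)
    rows = []
    for s, l, p in grid:
        if l > s or s + p > n_train or min(s, p) < 1 or l < 0:
            logger.warning("skipping invalid window combination (s=%s, l=%s, p=%s)", s, l, p)
            continue
        c = PipelineConfig(seq_len=s, label_len=l, pred_len=p, period=cfg.period,
                           seasonal_smoother=cfg.seasonal_smoother,
                           train_stride=cfg.train_stride, residual=cfg.residual,
                           trend=cfg.trend)
        model, params = train_direct_informer(series, target_channel, c,
                                              seed=seed, n_train=n_train)
        m = evaluate_direct_informer(model, params, series, target_channel, c,
                                     test_start=n_train, stride=eval_stride)
        rows.append({"seq_len": s, "label_len": l, "pred_len": p, "MSE": m["MSE"]})
    return pd.DataFrame(rows)


def full_sweep_grid() -> list[tuple[int, int, int]]:
    """The full sweep grid: seq 24/36/48/72/84 × label n−24, n−12 × pred 7/9/12."""
    return [(s, l, p)
            for s in (24, 36, 48, 72, 84)
            for l in (s - 24, s - 12)
            for p in (7, 9, 12)]


def _svr_baseline(train_wb: WindowBatch, test_wb: WindowBatch) -> np.ndarray:
    from sklearn.multioutput import MultiOutputRegressor
    from sklearn.svm import SVR

    Xtr = train_wb.enc_x.reshape(train_wb.n_windows, -1)
    Xte = test_wb.enc_x.reshape(test_wb.n_windows, -1)
    reg = MultiOutputRegressor(SVR())
    reg.fit(Xtr, train_wb.target)
    return reg.predict(Xte)


def _xgboost_baseline(train_wb: WindowBatch, test_wb: WindowBatch) -> np.ndarray:
    from sklearn.multioutput import MultiOutputRegressor
    from xgboost import XGBRegressor

    Xtr = train_wb.enc_x.reshape(train_wb.n_windows, -1)
    Xte = test_wb.enc_x.reshape(test_wb.n_windows, -1)
    reg = MultiOutputRegressor(XGBRegressor(n_estimators=50, max_depth=4,
                                            verbosity=0))
    reg.fit(Xtr, train_wb.target)
    return reg.predict(Xte)


BASELINES = {"SVR": _svr_baseline, "XGBoost": _xgboost_baseline}


def run_model_comparison(series: RegularSeries, target_channel: str,
                         cfg: PipelineConfig | None = None, seed: int = 0,
                         n_train: int | None = None,
                         models: tuple[str, ...] = ("Informer", "SVR", "Proposed model"),
                         eval_stride: int = 1) -> pd.DataFrame:
    """MAE/MSE/RMSE comparison table (normalized scale) for one target.

    ``models`` may contain "Proposed model" (the decomposition pipeline),
    "Informer" (direct), and any key of :data:`BASELINES` ("SVR",
    "XGBoost").  Baseline defaults are documented, not tuned to match any
    published cells.
    """
    cfg = cfg or PipelineConfig()
    n_train = n_train or int(series.n_samples * 8 / 9)
    series = impute_missing(series)
    rows = []
    params = fit_normalizer(series, slice(0, n_train))
    train_wb = _normalized_windows(series, params, cfg.seq_len, cfg.label_len,
                                   cfg.pred_len, target_channel,
                                   stride=cfg.train_stride, hi=n_train)
    test_wb = _normalized_windows(series, params, cfg.seq_len, cfg.label_len,
                                  cfg.pred_len, target_channel, stride=eval_stride,
                                  lo=n_train - cfg.seq_len)
    for name in models:
        if name == "Proposed model":
            pipe = fit_pipeline(series, target_channel, cfg, seed=seed, n_train=n_train)
            m = evaluate_pipeline(pipe, stride=eval_stride)
            m = {k: m[k] for k in ("MAE", "MSE", "RMSE")}
        elif name == "Informer":
            model, params_i = train_direct_informer(series, target_channel, cfg,
                                                    seed=seed, n_train=n_train)
            m = evaluate_direct_informer(model, params_i, series, target_channel,
                                         cfg, test_start=n_train, stride=eval_stride)
            m = {k: m[k] for k in ("MAE", "MSE", "RMSE")}
        elif name in BASELINES:
            preds = BASELINES[name](train_wb, test_wb)
            m = compute_metrics(test_wb.target, preds)
        else:
            raise ValueError(f"unknown model {name!r}")
        rows.append({"model": name, "target": target_channel, **m})
    return pd.DataFrame(rows)


def run_ablation(series: RegularSeries, target_channel: str,
                 input_subsets: list[list[str]], cfg: PipelineConfig | None = None,
                 seed: int = 0, n_train: int | None = None,
                 eval_stride: int = 1) -> pd.DataFrame:
    """Metrics per input subset + improvement of the largest subset's run.

    Mirrors the input-cardinality experiment: the pipeline takes one, two or
    three channel types as input and predicts one target.  Improvement rows
    report the percent reduction of each metric achieved by the final
    (largest) subset relative to each other subset.
    """
    cfg = cfg or PipelineConfig()
    if any(len(s) == 0 for s in input_subsets):
        raise ValueError("empty input subset")
    rows = []
    for subset in input_subsets:
        pipe = fit_pipeline(series, target_channel, cfg, seed=seed,
                            input_channels=list(subset), n_train=n_train)
        m = evaluate_pipeline(pipe, stride=eval_stride)
        rows.append({"inputs": "+".join(subset), "kind": "metrics",
                     "MAE": m["MAE"], "MSE": m["MSE"], "RMSE": m["RMSE"]})
    full = rows[-1]
    out = list(rows)
    for r in rows[:-1]:
        out.append({
            "inputs": f"{full['inputs']} vs {r['inputs']}", "kind": "improvement_pct",
            **{k: 100.0 * (r[k] - full[k]) / r[k] if r[k] else 0.0
               for k in ("MAE", "MSE", "RMSE")},
        })
    return pd.DataFrame(out)
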