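"""Reading, cleaning, normalizing, splitting and windowing regular series.

The pipeline's raw input is a multivariate environmental time series sampled
on a fixed grid (default 10 minutes): temperature (°C), relative humidity
(%rh) and CO2 concentration (ppm) from a closed livestock house.  This module
owns everything between a CSV on disk and the model-ready window tensors:

* :class:`RegularSeries` — timestamp grid + channel matrix + missing mask;
* neighbour-mean imputation of missing cells;
* min–max normalization fitted on the training slice only;
* chronological train/test splitting;
* calendar time features for the attention model's embedding;
* sliding-window extraction into :class:`WindowBatch` with the
  (seq_len, label_len, pred_len) convention of encoder–decoder forecasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegularSeries",
    "NormalizationParams",
    "WindowBatch",
    "build_time_grid",
    "impute_missing",
    "fit_normalizer",
    "normalize",
    "denormalize",
    "split_train_test",
    "time_features",
    "make_windows",
    "read_series_csv",
    "write_series_csv",
    "load_config",
]

N_TIME_FEATURES = 5  # month, day-of-month, weekday, hour, minute


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RegularSeries:
    """A multivariate series on a strictly regular timestamp grid.

    ``values`` is ``[n_samples, n_channels]`` in the physical units of each
    channel; ``missing_mask`` marks cells that were originally missing (True =
    missing).  After :func:`impute_missing` the values are finite everywhere
    but the mask still records where the original observations were absent.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    channel_names: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [n_samples, n_channels]")
        if len(self.timestamps) != self.values.shape[0]:
            raise ValueError("timestamps and values disagree on n_samples")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names and values disagree on n_channels")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(self.timestamps) > 1:
            steps = np.diff(self.timestamps.asi8)
            if not (steps > 0).all() or len(set(steps)) > 1:
                raise ValueError("timestamps must be strictly increasing on a fixed step")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]

    def select_channels(self, names: list[str]) -> "RegularSeries":
        idx = [self.channel_names.index(n) for n in names]
        return RegularSeries(
            timestamps=self.timestamps,
            values=self.values[:, idx].copy(),
            channel_names=list(names),
            missing_mask=self.missing_mask[:, idx].copy(),
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel min–max bounds, fitted on the training slice only."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x_min", np.asarray(self.x_min, dtype=np.float64))
        object.__setattr__(self, "x_max", np.asarray(self.x_max, dtype=np.float64))
        if not (self.x_max > self.x_min).all():
            raise ValueError("x_max must exceed x_min in every channel")


@dataclass
class WindowBatch:
    """Model-ready sliding windows.

    ``enc_x``: [B, seq_len, C_in] encoder input.
    ``dec_x``: [B, label_len + pred_len, C_in]; the first ``label_len`` rows
    repeat the tail of the encoder window, the last ``pred_len`` rows are zero
    placeholders for the one-shot generative decoder.
    ``target``: [B, pred_len] future values of the target channel.
    ``enc_time``/``dec_time``: matching calendar-feature matrices.
    """

    enc_x: np.ndarray
    dec_x: np.ndarray
    target: np.ndarray
    enc_time: np.ndarray
    dec_time: np.ndarray
    seq_len: int
    label_len: int
    pred_len: int

    def __post_init__(self):
        if not (self.seq_len > 0 and self.pred_len > 0 and self.label_len >= 0):
            raise ValueError("seq_len, pred_len must be positive; label_len >= 0")
        if self.label_len > self.seq_len:
            raise ValueError("label_len must not exceed seq_len")

    @property
    def n_windows(self) -> int:
        return self.enc_x.shape[0]

    def subset(self, idx) -> "WindowBatch":
        return replace(
            self,
            enc_x=self.enc_x[idx],
            dec_x=self.dec_x[idx],
            target=self.target[idx],
            enc_time=self.enc_time[idx],
            dec_time=self.dec_time[idx],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_time_grid(start, end, step_minutes: int = 10) -> pd.DatetimeIndex:
    """Inclusive regular timestamp grid from ``start`` to ``end``.

    The acquisition convention: 10-minute sampling from 00:00 on the first day
    to 23:50 on the last yields 144 samples per day.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end < start:
        raise ValueError("end precedes start")
    step = pd.Timedelta(minutes=step_minutes)
    span = end - start
    if span % step != pd.Timedelta(0):
        raise ValueError("step does not divide the interval")
    return pd.date_range(start, end, freq=step)


def impute_missing(series: RegularSeries) -> RegularSeries:
    """Fill missing cells from their temporal neighbours.

    An isolated gap gets the mean of the flanking observed values; interior
    runs of two or more get linear interpolation between the flanking values
    (the natural generalization of the neighbour mean); missing values at the
    boundary copy the nearest observed value.  Observed cells are never
    altered; the original missing mask is preserved.
    """
    vals = series.values.copy()
    vals[series.missing_mask] = np.nan
    for c in range(series.n_channels):
        col = vals[:, c]
        if np.isnan(col).all():
            raise ValueError(
                f"channel {series.channel_names[c]!r} has no observed values"
            )
    df = pd.DataFrame(vals)
    filled = df.interpolate(method="linear", limit_direction="both", axis=0)
    out = filled.to_numpy()
    # interpolation must leave observed cells untouched
    obs = ~series.missing_mask
    out[obs] = series.values[obs]
    return RegularSeries(
        timestamps=series.timestamps,
        values=out,
        channel_names=list(series.channel_names),
        missing_mask=series.missing_mask.copy(),
    )


def fit_normalizer(series: RegularSeries, train_slice: slice | None = None) -> NormalizationParams:
    """Per-channel min/max over the training slice only (no test leakage)."""
    sl = train_slice if train_slice is not None else slice(None)
    train = series.values[sl]
    if train.shape[0] == 0:
        raise ValueError("training slice is empty")
    x_min = train.min(axis=0)
    x_max = train.max(axis=0)
    if not (x_max > x_min).all():
        bad = [series.channel_names[i] for i in np.nonzero(x_max <= x_min)[0]]
        raise ValueError(f"constant channel(s) in training slice: {bad}")
    return NormalizationParams(x_min=x_min, x_max=x_max)


def normalize(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Min–max scaling ``y = (x − x_min) / (x_max − x_min)``.

    In-range values map to [0, 1]; test values outside the training range are
    allowed to map outside it.
    """
    return (np.asarray(x, dtype=np.float64) - params.x_min) / (params.x_max - params.x_min)


def denormalize(y: np.ndarray, params: NormalizationParams) -> np.ndarray:
    return np.asarray(y, dtype=np.float64) * (params.x_max - params.x_min) + params.x_min


def split_train_test(series: RegularSeries, n_train: int) -> tuple[RegularSeries, RegularSeries]:
    """Chronological split: first ``n_train`` samples train, the rest test."""
    if not 0 < n_train < series.n_samples:
        raise ValueError("n_train must satisfy 0 < n_train < n_samples")
    def cut(sl: slice) -> RegularSeries:
        return RegularSeries(
            timestamps=series.timestamps[sl],
            values=series.values[sl].copy(),
            channel_names=list(series.channel_names),
            missing_mask=series.missing_mask[sl].copy(),
        )
    return cut(slice(0, n_train)), cut(slice(n_train, series.n_samples))


def time_features(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Calendar features per timestamp, each scaled into [−0.5, 0.5].

    Columns: month, day-of-month, weekday (Monday = 0), hour, minute.  These
    are the covariates the attention model's embedding projects and adds to
    the value embedding.
    """
    ts = pd.DatetimeIndex(timestamps)
    feats = np.column_stack(
        [
            (ts.month.to_numpy() - 1) / 11.0 - 0.5,
            (ts.day.to_numpy() - 1) / 30.0 - 0.5,
            ts.dayofweek.to_numpy() / 6.0 - 0.5,
            ts.hour.to_numpy() / 23.0 - 0.5,
            ts.minute.to_numpy() / 59.0 - 0.5,
        ]
    )
    return feats.astype(np.float64)


def make_windows(
    series: RegularSeries,
    seq_len: int,
    label_len: int,
    pred_len: int,
    target_channel: str,
    stride: int = 1,
    values: np.ndarray | None = None,
) -> WindowBatch:
    """Cut sliding windows for encoder–decoder training.

    Window starting at ``i``: the encoder sees rows ``[i, i+seq_len)``; the
    decoder context repeats rows ``[i+seq_len−label_len, i+seq_len)`` followed
    by ``pred_len`` zero rows; the target is the next ``pred_len`` values of
    ``target_channel``.  With stride 1 the window count is
    ``n − seq_len − pred_len + 1``.

    ``values`` overrides the matrix to window (e.g. a component matrix on the
    same grid) while timestamps and channel names come from ``series``.
    """
    if label_len > seq_len:
        raise ValueError("label_len must not exceed seq_len")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x = series.values if values is None else np.asarray(values, dtype=np.float64)
    if x.shape != series.values.shape:
        raise ValueError("values override must match the series shape")
    n = x.shape[0]
    if seq_len + pred_len > n:
        raise ValueError("series too short for seq_len + pred_len")
    tgt = series.channel_names.index(target_channel)
    feats = time_features(series.timestamps)

    starts = np.arange(0, n - seq_len - pred_len + 1, stride)
    B = len(starts)
    C = x.shape[1]
    enc_x = np.empty((B, seq_len, C))
    dec_x = np.zeros((B, label_len + pred_len, C))
    target = np.empty((B, pred_len))
    enc_time = np.empty((B, seq_len, feats.shape[1]))
    dec_time = np.empty((B, label_len + pred_len, feats.shape[1]))
    for b, i in enumerate(starts):
        e = i + seq_len
        enc_x[b] = x[i:e]
        if label_len:
            dec_x[b, :label_len] = x[e - label_len : e]
        target[b] = x[e : e + pred_len, tgt]
        enc_time[b] = feats[i:e]
        dec_time[b] = feats[e - label_len : e + pred_len]
    return WindowBatch(
        enc_x=enc_x,
        dec_x=dec_x,
        target=target,
        enc_time=enc_time,
        dec_time=dec_time,
        seq_len=seq_len,
        label_len=label_len,
        pred_len=pred_len,
    )


# ---------------------------------------------------------------------------
# external interfaces: CSV and YAML config
# ---------------------------------------------------------------------------

def read_series_csv(path: str | Path, timestamp_column: str = "timestamp") -> RegularSeries:
    """Read a RegularSeries from CSV (header row, ISO-8601 timestamps,
    '.' decimal; missing cells empty or "NaN")."""
    df = pd.read_csv(path, parse_dates=[timestamp_column])
    ts = pd.DatetimeIndex(df[timestamp_column])
    chans = [c for c in df.columns if c != timestamp_column]
    vals = df[chans].to_numpy(dtype=np.float64)
    return RegularSeries(timestamps=ts, values=vals, channel_names=chans)


def write_series_csv(series: RegularSeries, path: str | Path) -> None:
    vals = series.values.copy()
    vals[series.missing_mask] = np.nan
    df = pd.DataFrame(vals, columns=series.channel_names)
    df.insert(0, "timestamp", series.timestamps)
    df.to_csv(path, index=False)


DEFAULT_CONFIG = {
    "channels": ["temperature", "humidity", "co2"],
    "step_minutes": 10,
    "seq_len": 24,
    "label_len": 12,
    "pred_len": 7,
    "n_train": 7680,
    "target_channel": "co2",
}


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML run configuration, filling defaults for absent keys."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return cfg
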