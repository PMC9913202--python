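"""Synthetic rabbit-house microclimate series.

The study data (60 days of temperature / relative humidity / CO2 at
10-minute sampling from a closed rabbit house) are not publicly deposited,
so every stage of the package is exercised on a generator that emulates
their published structure: marginal means/SDs/ranges, a strong 24-hour
diurnal cycle with temperature in anti-phase to humidity and CO2, slow trend
drift, autocorrelated noise whose cross-channel coupling reproduces the
published Pearson matrix, small independent sensor noise, and injectable
missing values.

Each channel is composed additively:

    x_i(t) = mean_i + diurnal_i(t) + drift_i·t + ar_i(t) + sensor_i(t)

where ``diurnal_i`` is a sinusoid (channel-specific peak hour, optional
second harmonic), ``ar_i`` is an AR(1) process whose innovations are coupled
across channels through a Cholesky factor, and ``sensor_i`` is independent
white measurement noise.  The innovation correlation matrix is solved
analytically from the target series correlations given each channel's
diurnal variance share, so the realized Pearson matrix lands near the target
(tolerance ±0.1 at a month of data; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import RegularSeries, build_time_grid

__all__ = ["SyntheticSpec", "generate", "inject_missing", "TABLE_TARGETS"]

# Published descriptive statistics of the rabbit-house channels
# (range, mean, SD) and their Pearson correlation matrix.
TABLE_TARGETS = {
    "channel_names": ["temperature", "humidity", "co2"],
    "units": ["degC", "pct_rh", "ppm"],
    "means": [19.09, 66.03, 802.23],
    "sds": [2.79, 8.86, 250.82],
    "ranges": [(9.3, 25.57), (32.42, 84.3), (138.75, 1858.57)],
    "corr": [[1.0, -0.8276, -0.5149],
             [-0.8276, 1.0, 0.6505],
             [-0.5149, 0.6505, 1.0]],
}


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults reproduce the published acquisition: 8640 samples (60 days at
    10-minute steps), period 144, marginals and correlation targets from the
    published tables, temperature peaking mid-afternoon with humidity and CO2
    in anti-phase.  ``diurnal_share`` is the fraction of each channel's
    variance carried by the daily cycle (temperature strongly diurnal, CO2
    dominated by irregular fluctuation); ``sensor_noise_share`` is the small
    independent measurement-noise fraction per recorder.
    """

    n_samples: int = 8640
    step_minutes: int = 10
    period: int = 144
    start: str = "2020-09-30 00:00"
    channel_names: list[str] = field(default_factory=lambda: list(TABLE_TARGETS["channel_names"]))
    means: list[float] = field(default_factory=lambda: list(TABLE_TARGETS["means"]))
    sds: list[float] = field(default_factory=lambda: list(TABLE_TARGETS["sds"]))
    target_corr: list[list[float]] = field(default_factory=lambda: [row[:] for row in TABLE_TARGETS["corr"]])
    peak_hours: list[float] = field(default_factory=lambda: [15.0, 3.0, 3.0])
    second_harmonic: float = 0.0
    diurnal_share: list[float] = field(default_factory=lambda: [0.5, 0.4, 0.15])
    sensor_noise_share: list[float] = field(default_factory=lambda: [0.05, 0.05, 0.05])
    ar_coeff: float = 0.9
    drift_per_day: list[float] = field(default_factory=lambda: [-0.02, 0.05, 2.0])
    clip_to_range: bool = False
    ranges: list[tuple[float, float]] = field(default_factory=lambda: list(TABLE_TARGETS["ranges"]))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.target_corr, dtype=np.float64)
        if R.shape[0] != R.shape[1] or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("target correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("target correlation matrix is not positive semidefinite")
        if self.n_samples < 2 * self.period:
            raise ValueError("n_samples must cover at least two seasonal cycles")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in [0, 1)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def _innovation_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Solve the AR-innovation correlation from the series-level targets.

    Series covariance splits as cov_ij = s_i s_j ρ_sin,ij + a_i a_j ρ_ar,ij
    (sensor noise is independent), with s the diurnal RMS amplitudes, a the
    AR stationary SDs and ρ_sin,ij = cos(Δphase).  Solving for ρ_ar and
    clipping into [−1, 1]; if the result is indefinite its spectrum is
    clipped at zero and the diagonal renormalized.
    """
    C = spec.n_channels
    sds = np.asarray(spec.sds)
    w = np.asarray(spec.diurnal_share)
    m = np.asarray(spec.sensor_noise_share)
    T = np.asarray(spec.target_corr)
    s = sds * np.sqrt(w)                       # diurnal RMS
    a = sds * np.sqrt(np.clip(1.0 - w - m, 0.0, None))  # AR stationary SD
    phase = 2 * np.pi * np.asarray(spec.peak_hours) / 24.0
    rho_sin = np.cos(phase[:, None] - phase[None, :])
    R = np.eye(C)
    for i in range(C):
        for j in range(i + 1, C):
            if a[i] == 0.0 or a[j] == 0.0:
                continue  # no AR noise in one of the channels
            num = T[i, j] * sds[i] * sds[j] - s[i] * s[j] * rho_sin[i, j]
            R[i, j] = R[j, i] = np.clip(num / (a[i] * a[j]), -1.0, 1.0)
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < 0:
        R = evecs @ np.diag(np.clip(evals, 1e-8, None)) @ evecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def generate(spec: SyntheticSpec | None = None) -> RegularSeries:
    """Generate one synthetic series; deterministic for a fixed seed."""
    spec = spec or SyntheticSpec()
    C = spec.n_channels
    n = spec.n_samples
    rng = np.random.default_rng(spec.seed)
    start = pd.Timestamp(spec.start)
    end = start + pd.Timedelta(minutes=spec.step_minutes) * (n - 1)
    ts = build_time_grid(start, end, spec.step_minutes)

    sds = np.asarray(spec.sds)
    w = np.asarray(spec.diurnal_share)
    mshare = np.asarray(spec.sensor_noise_share)
    hours = (np.arange(n) * spec.step_minutes / 60.0) + start.hour + start.minute / 60.0

    # diurnal component: amplitude from the variance share (RMS = amp/√2)
    amp = sds * np.sqrt(2.0 * w)
    diurnal = np.empty((n, C))
    for c in range(C):
        ph = 2 * np.pi * (hours - spec.peak_hours[c]) / 24.0
        wave = np.cos(ph) + spec.second_harmonic * np.cos(2 * ph)
        if spec.second_harmonic:
            wave = wave / np.sqrt(1.0 + spec.second_harmonic**2)  # keep unit RMS·√2
        diurnal[:, c] = amp[c] * wave

    # coupled AR(1) noise
    a_sd = sds * np.sqrt(np.clip(1.0 - w - mshare, 0.0, None))
    phi = spec.ar_coeff
    innov_sd = a_sd * np.sqrt(1.0 - phi**2)
    L = np.linalg.cholesky(_innovation_correlation(spec) + 1e-12 * np.eye(C))
    z = rng.standard_normal((n, C)) @ L.T * innov_sd
    ar = np.empty((n, C))
    ar[0] = rng.standard_normal(C) * a_sd  # stationary start
    for t in range(1, n):
        ar[t] = phi * ar[t - 1] + z[t]

    sensor = rng.standard_normal((n, C)) * (sds * np.sqrt(mshare))

    days = np.arange(n) / spec.period
    drift = np.outer(days - days.mean(), np.asarray(spec.drift_per_day))

    values = np.asarray(spec.means) + diurnal + drift + ar + sensor
    if spec.clip_to_range:
        for c, (lo, hi) in enumerate(spec.ranges):
            values[:, c] = np.clip(values[:, c], lo, hi)

    series = RegularSeries(timestamps=ts, values=values,
                           channel_names=list(spec.channel_names))
    if spec.missing_rate > 0:
        series = inject_missing(series, spec.missing_rate, seed=spec.seed + 1)
    return series


def inject_missing(series: RegularSeries, rate: float, seed: int = 0) -> RegularSeries:
    """Mark ⌊rate · n_cells⌋ random cells missing (never an entire channel)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n, C = series.values.shape
    k = int(rate * n * C)
    if k == 0:
        return series
    rng = np.random.default_rng(seed)
    flat = rng.choice(n * C, size=k, replace=False)
    mask = series.missing_mask.copy()
    mask[flat // C, flat % C] = True
    for c in range(C):  # keep at least one observation per channel
        if mask[:, c].all():
            mask[rng.integers(n), c] = False
    vals = series.values.copy()
    vals[mask] = np.nan
    return RegularSeries(timestamps=series.timestamps, values=vals,
                         channel_names=list(series.channel_names),
                         missing_mask=mask)
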