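"""STL decomposition of each channel and forward projection of the seasonal.

Livestock-house microclimate series are non-stationary with a strong 24-hour
diurnal cycle (144 samples at 10-minute sampling).  Each channel is split
additively into trend + seasonal + residual with STL (Seasonal and Trend
decomposition using Loess); the slowly varying trend and the irregular
residual are forecast by separate models, while the seasonal component is
treated as a periodic constant and simply tiled forward.

The LOESS inner/outer loops are delegated to
:class:`statsmodels.tsa.seasonal.STL`; what this package owns is the contract
(exact additive reconstruction, near-zero cycle mean of the seasonal) and the
projection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.seasonal import STL

__all__ = ["DecompositionResult", "stl_decompose", "project_seasonal", "decompose_series"]

DEFAULT_PERIOD = 144  # 24 h at 10-minute sampling
DEFAULT_SEASONAL_SMOOTHER = 25
# A long seasonal LOESS span keeps the estimated cycle close to the "periodic
# constant" the projection step assumes; 25 (in cycle units, odd) is the
# default and is overridable per call / via config.


@dataclass
class DecompositionResult:
    """Additive trend/seasonal/residual split of one channel.

    Invariant: ``trend + seasonal + residual`` reconstructs the input to
    within 1e-8 absolute; ``period`` is the samples per seasonal cycle.
    """

    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray
    period: int

    def __post_init__(self):
        if self.period < 2:
            raise ValueError("period must be >= 2")
        n = len(self.trend)
        if not (len(self.seasonal) == n == len(self.residual)):
            raise ValueError("component lengths disagree")

    @property
    def n(self) -> int:
        return len(self.trend)

    def reconstruct(self) -> np.ndarray:
        return self.trend + self.seasonal + self.residual


def stl_decompose(
    channel: np.ndarray,
    period: int = DEFAULT_PERIOD,
    robust: bool = True,
    seasonal_smoother: int = DEFAULT_SEASONAL_SMOOTHER,
) -> DecompositionResult:
    """Decompose one channel into trend + seasonal + residual.

    Parameters
    ----------
    channel
        1-D array without missing values, length >= 2 * period.
    period
        Samples per seasonal cycle (144 for a diurnal cycle at 10-min steps).
    robust
        Use robustness (outer-loop) weights; on by default because CO2
        residuals carry large outliers.
    seasonal_smoother
        Odd LOESS span (in cycle units) for the seasonal sub-series.
    """
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("channel must be 1-D")
    if np.isnan(x).any():
        raise ValueError("channel contains missing values; impute first")
    if len(x) < 2 * period:
        raise ValueError("series shorter than two seasonal cycles")
    if seasonal_smoother % 2 == 0:
        raise ValueError("seasonal_smoother must be odd")
    fit = STL(x, period=period, seasonal=seasonal_smoother, robust=robust).fit()
    return DecompositionResult(
        trend=np.asarray(fit.trend),
        seasonal=np.asarray(fit.seasonal),
        residual=np.asarray(fit.resid),
        period=period,
    )


def project_seasonal(result: DecompositionResult, horizon: int, anchor: int | None = None) -> np.ndarray:
    """Seasonal values for the ``horizon`` positions following ``anchor``.

    The seasonal component is treated as a periodic constant: the last full
    estimated cycle is tiled forward, so position ``anchor + k`` receives the
    cycle value at phase ``(anchor + k) mod period`` taken from the final
    complete cycle.  ``anchor`` defaults to the end of the series (forecast
    continuation).
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    n, period = result.n, result.period
    if anchor is None:
        anchor = n
    if not 0 <= anchor <= n:
        raise ValueError("anchor outside the series")
    if horizon == 0:
        return np.empty(0)
    # last full cycle aligned to phase 0
    last_start = (n // period - 1) * period
    cycle = result.seasonal[last_start : last_start + period]
    phases = (anchor + np.arange(horizon)) % period
    return cycle[phases]


def decompose_series(values: np.ndarray, period: int = DEFAULT_PERIOD,
                     robust: bool = True,
                     seasonal_smoother: int = DEFAULT_SEASONAL_SMOOTHER) -> list[DecompositionResult]:
    """STL per column of a [n, C] matrix."""
    values = np.asarray(values, dtype=np.float64)
    return [
        stl_decompose(values[:, c], period=period, robust=robust,
                      seasonal_smoother=seasonal_smoother)
        for c in range(values.shape[1])
    ]
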