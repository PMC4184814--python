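"""Univariate early-warning indicators in rolling windows.

Rising variance, skewness and kurtosis can indicate flickering between
alternative states; rising lag-1 autocorrelation indicates critical
slowing down.  All indicators are computed per species over trailing
windows (default 10 time steps), anchored at the window's last time step
so no indicator ever uses future data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import CommunityTimeSeries

__all__ = ["INDICATORS", "IndicatorSeries", "rolling_indicator", "indicators_all_species"]

INDICATORS = ("variance", "skewness", "kurtosis", "ac1")


@dataclass
class IndicatorSeries:
    """One indicator track for one species."""

    species: str
    indicator: str
    window: int
    ages: np.ndarray   # anchor age = last age in each window
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "species": self.species,
                "indicator": self.indicator,
                "value": self.values,
            }
        )


def _window_values(x: np.ndarray, window: int, indicator: str, ddof: int) -> np.ndarray:
    W = sliding_window_view(x, window)
    mean = W.mean(axis=1, keepdims=True)
    dev = W - mean
    m2 = (dev**2).mean(axis=1)          # population central moments
    zero = m2 == 0.0

    if indicator == "variance":
        return (dev**2).sum(axis=1) / (window - ddof)

    with np.errstate(divide="ignore", invalid="ignore"):
        if indicator == "skewness":
            out = (dev**3).mean(axis=1) / m2**1.5
        elif indicator == "kurtosis":
            out = (dev**4).mean(axis=1) / m2**2
        elif indicator == "ac1":
            a, b = W[:, :-1], W[:, 1:]
            a = a - a.mean(axis=1, keepdims=True)
            b = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
            out = (a * b).sum(axis=1) / denom
            zero = denom == 0.0
        else:
            raise ValueError(f"unknown indicator {indicator!r}")
    out[zero] = np.nan
    return out


def rolling_indicator(
    x: np.ndarray,
    window: int,
    indicator: str,
    ages: np.ndarray | None = None,
    species: str = "",
    ddof: int = 1,
) -> IndicatorSeries:
    """Compute one rolling indicator over a 1-D abundance series.

    Definitions per window: variance = sample variance (``ddof=1`` by
    default, ``ddof=0`` for the population form); skewness = moment
    skewness ``m3/m2^1.5`` (bias-uncorrected); kurtosis = raw Pearson
    kurtosis ``m4/m2**2`` (not excess); ``ac1`` = Pearson correlation of
    the ``window-1`` pairs ``(x_t, x_{t+1})`` inside the window.  Windows
    with zero variance yield NaN for skewness/kurtosis/ac1 (variance is 0).

    Values are anchored to the window's last time step.
    """
    x = np.asarray(x, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    if len(x) < window:
        raise ValueError(f"series of length {len(x)} shorter than window {window}")
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
    values = _window_values(x, window, indicator, ddof)
    if ages is None:
        anchor = np.arange(window - 1, len(x), dtype=float)
    else:
        anchor = np.asarray(ages, dtype=float)[window - 1:]
    return IndicatorSeries(species, indicator, window, anchor, values)


def indicators_all_species(
    cts: CommunityTimeSeries, window: int = 10, ddof: int = 1
) -> pd.DataFrame:
    """All four indicators for every species, as a long-format table.

    Returns a DataFrame with columns (age, species, indicator, value),
    one row per (window, species, indicator) — i.e. ``4 * n_species``
    indicator series of length ``n_steps - window + 1`` each.
    """
    frames = []
    for j, name in enumerate(cts.species_names):
        for ind in INDICATORS:
            frames.append(
                rolling_indicator(
                    cts.abundance[:, j], window, ind, ages=cts.ages, species=name,
                    ddof=ddof,
                ).to_frame()
            )
    return pd.concat(frames, ignore_index=True)
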