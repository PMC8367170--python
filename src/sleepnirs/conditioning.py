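"""Signal conditioning for tissue-oximetry time series.

Two stages, applied to the StO2 / concentration series after inversion:
a zero-phase FIR low-pass below 0.08 Hz (Hanning-window design) to strip
cardiac, respiratory and slow hemodynamic oscillations, followed by
robust locally weighted scatterplot smoothing (LOWESS, tricube weights
with bisquare robustness iterations).

Quality-gated samples are carried as a gap mask: they are bridged by
linear interpolation before the convolution (never zero-filled, which
would bleed spurious steps into neighbouring samples) and excluded from
the LOWESS regressions; the mask is preserved on the output so that
event extraction can keep ignoring them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import firwin
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ConfigurationError, ValidationError

__all__ = ["UniformSeries", "design_lowpass", "lowpass_zero_phase", "lowess_smooth"]

#: default transition-band width (Hz) used to pick the filter order
DEFAULT_TRANSITION_HZ = 0.05


@dataclass
class UniformSeries:
    """A uniformly sampled series with a gap mask for excluded samples."""

    start_time_s: float
    sampling_rate_hz: float
    values: np.ndarray
    gap_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if not (self.sampling_rate_hz > 0):
            raise ValidationError("sampling_rate_hz must be positive")
        if self.gap_mask.shape != self.values.shape:
            raise ValidationError("gap_mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.gap_mask])):
            raise ValidationError("values must be finite where gap_mask is clear")

    @property
    def time_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.values.size) / self.sampling_rate_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + (self.values.size - 1) / self.sampling_rate_hz

    def copy_with(self, values: np.ndarray) -> "UniformSeries":
        return UniformSeries(
            start_time_s=self.start_time_s,
            sampling_rate_hz=self.sampling_rate_hz,
            values=values,
            gap_mask=self.gap_mask.copy(),
        )


def _bridge_gaps(values: np.ndarray, gap: np.ndarray) -> np.ndarray:
    """Linear interpolation (edge hold) across gap-masked samples."""
    if not gap.any():
        return values
    if gap.all():
        raise ValidationError("series is entirely gap-masked")
    out = values.copy()
    idx = np.arange(values.size)
    out[gap] = np.interp(idx[gap], idx[~gap], values[~gap])
    return out


def design_lowpass(
    cutoff_hz: float,
    sampling_rate_hz: float,
    numtaps: Optional[int] = None,
    transition_hz: float = DEFAULT_TRANSITION_HZ,
) -> np.ndarray:
    """Design the linear-phase Hanning-window low-pass FIR.

    The default order is chosen so the transition band is about
    ``transition_hz`` wide (a Hann window needs roughly 3.1/N of
    normalized bandwidth to roll off), giving 323 taps at the 5.2 Hz /
    0.08 Hz defaults.  Odd tap count keeps the group delay an integer
    number of samples so the centered convolution is exactly zero-phase.
    """
    if not (0 < cutoff_hz < sampling_rate_hz / 2):
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sampling_rate_hz / 2} Hz)"
        )
    if numtaps is None:
        numtaps = int(round(3.1 * sampling_rate_hz / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    if numtaps < 3:
        raise ConfigurationError("numtaps must be at least 3")
    return firwin(numtaps, cutoff_hz, window="hann", fs=sampling_rate_hz)


def lowpass_zero_phase(
    series: UniformSeries,
    cutoff_hz: float = 0.08,
    numtaps: Optional[int] = None,
    transition_hz: float = DEFAULT_TRANSITION_HZ,
) -> UniformSeries:
    """Zero-phase low-pass: centered symmetric convolution with reflection padding.

    A symmetric (linear-phase) FIR applied centered introduces no phase
    shift at any frequency; reflection padding avoids edge transients in
    event windows near the recording boundaries.  Gap-masked samples are
    bridged by interpolation for the convolution and stay masked on the
    output.
    """
    taps = design_lowpass(cutoff_hz, series.sampling_rate_hz, numtaps, transition_hz)
    n = series.values.size
    if n <= taps.size:
        raise ValidationError(
            f"series of {n} samples is shorter than the {taps.size}-tap filter"
        )
    x = _bridge_gaps(series.values, series.gap_mask)
    pad = taps.size // 2
    xp = np.pad(x, pad, mode="reflect")
    y = np.convolve(xp, taps, mode="valid")
    return series.copy_with(y)


def lowess_smooth(
    series: UniformSeries,
    span: float = 0.1,
    robust_iters: int = 2,
    delta_s: float = 0.0,
) -> UniformSeries:
    """Robust LOWESS smoothing (tricube weights, bisquare robustness).

    ``span`` is the fraction of the (non-gap) samples in each local
    regression window; ``robust_iters`` bisquare reweighting passes
    suppress outliers such as residual motion spikes.  ``delta_s`` skips
    regressions for points closer than that many seconds to the last
    fitted one (linear interpolation in between) — essential for long
    recordings, exact when 0.  Output length equals input length; gap
    samples are excluded from the regressions and remain masked.
    """
    if not (0 < span <= 1):
        raise ConfigurationError(f"span must be in (0, 1], got {span}")
    if robust_iters < 0:
        raise ConfigurationError("robust_iters must be >= 0")
    good = ~series.gap_mask
    n_good = int(good.sum())
    if n_good == 0:
        raise ValidationError("series is entirely gap-masked")
    if int(math.ceil(span * n_good)) < 2:
        raise ConfigurationError(
            f"span {span} leaves a local window of fewer than 2 of the {n_good} samples"
        )
    t = series.time_s
    fitted = _sm_lowess(
        series.values[good],
        t[good],
        frac=span,
        it=robust_iters,
        delta=max(0.0, delta_s),
        is_sorted=True,
        return_sorted=False,
    )
    out = series.values.copy()
    out[good] = fitted
    return series.copy_with(out)
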