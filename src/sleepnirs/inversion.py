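"""Multidistance slope fitting, quality gating and tissue-oximetry inversion.

Per timepoint and wavelength, ordinary least squares of ``ln(r^2 I_AC)``,
``ln(r^2 I_DC)`` and ``phi`` against the source-detector distance ``r``
yields the three slopes of the diffusion model.  The (S_AC, S_phi) pair
is inverted to the absorption and reduced-scattering coefficients, the
two-wavelength absorption pair is unmixed into HbO2/HHb concentrations,
and tissue saturation follows from their ratio.

Quality gate: a sample is discarded when the regression R^2 of the
modulated amplitude or of the phase falls below 0.95 at either
wavelength — the signature of poor probe-skin contact or light shunting.
The DC R^2 is reported for diagnostics but not gated.  Samples whose
inversion comes out non-physical (mu_a <= 0 or mu_s' <= 0) are excluded
the same way and counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .optics import OpticalConfig, compute_sto2, invert_optical_properties, unmix_chromophores
from .simulate import RawOpticalData

__all__ = [
    "SlopeFitSeries",
    "fit_slopes",
    "qc_gate",
    "process_raw",
    "R2_MIN_DEFAULT",
]

logger = logging.getLogger(__name__)

R2_MIN_DEFAULT = 0.95


@dataclass
class SlopeFitSeries:
    """Per-timepoint, per-wavelength regression results (arrays (n_t, n_wl))."""

    time_s: np.ndarray
    wavelengths_nm: np.ndarray
    s_ac: np.ndarray
    s_dc: np.ndarray
    s_phi: np.ndarray
    c_ac: np.ndarray
    c_dc: np.ndarray
    c_phi: np.ndarray
    r2_ac: np.ndarray
    r2_dc: np.ndarray
    r2_phi: np.ndarray


def _ols_lastaxis(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, intercept and R^2 of y against x along the last axis.

    A constant y is a perfect (zero-slope) fit, so its R^2 is 1 by
    convention rather than the 0/0 the textbook formula would give.
    """
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    ybar = y.mean(axis=-1)
    slope = (y * xc).sum(axis=-1) / sxx
    intercept = ybar - slope * x.mean()
    sst = ((y - ybar[..., np.newaxis]) ** 2).sum(axis=-1)
    ssr = slope**2 * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 1.0)
    return slope, intercept, np.clip(r2, 0.0, 1.0)


def fit_slopes(raw: RawOpticalData, unwrap_phase: bool = True) -> SlopeFitSeries:
    """Fit the three multidistance regressions for every frame and wavelength.

    Raises ``DataError`` identifying (time, wavelength, distance) on
    non-positive intensities and ``ConfigurationError`` with fewer than 3
    distances.  Phases are defensively unwrapped across distances (2*pi
    jumps can survive instrument unwrapping); corrections are logged.
    """
    r = np.asarray(raw.distances_cm, dtype=float)
    if r.size < 3:
        raise ConfigurationError(
            f"slope regression needs >= 3 distances, got {r.size}"
        )
    for name, arr in (("i_ac", raw.i_ac), ("i_dc", raw.i_dc)):
        bad = ~(arr > 0)
        if bad.any():
            it, iw, ir = np.argwhere(bad)[0]
            raise DataError(
                f"non-positive {name} at time={raw.time_s[it]:.3f} s, "
                f"wavelength={raw.wavelengths_nm[iw]:g} nm, distance={r[ir]:g} cm"
            )
    phase = raw.phase_rad
    if unwrap_phase:
        unwrapped = np.unwrap(phase, axis=-1)
        n_fixed = int(np.sum(np.any(np.abs(unwrapped - phase) > 1e-9, axis=-1)))
        if n_fixed:
            logger.warning("unwrapped 2*pi phase jumps across distances in %d frames", n_fixed)
        phase = unwrapped

    y_ac = np.log(r**2 * raw.i_ac)
    y_dc = np.log(r**2 * raw.i_dc)
    s_ac, c_ac, r2_ac = _ols_lastaxis(r, y_ac)
    s_dc, c_dc, r2_dc = _ols_lastaxis(r, y_dc)
    s_phi, c_phi, r2_phi = _ols_lastaxis(r, phase)
    return SlopeFitSeries(
        time_s=raw.time_s,
        wavelengths_nm=raw.wavelengths_nm,
        s_ac=s_ac,
        s_dc=s_dc,
        s_phi=s_phi,
        c_ac=c_ac,
        c_dc=c_dc,
        c_phi=c_phi,
        r2_ac=r2_ac,
        r2_dc=r2_dc,
        r2_phi=r2_phi,
    )


def qc_gate(fit: SlopeFitSeries, r2_min: float = R2_MIN_DEFAULT) -> np.ndarray:
    """Per-frame pass flag: reject iff amplitude or phase R^2 < r2_min at any wavelength.

    Equality passes — the discard rule is strictly "smaller than".  The DC
    regression is not gated.
    """
    ok = (fit.r2_ac >= r2_min) & (fit.r2_phi >= r2_min)
    return ok.all(axis=-1)


def process_raw(
    raw: RawOpticalData,
    config: OpticalConfig,
    r2_min: float = R2_MIN_DEFAULT,
    fit: Optional[SlopeFitSeries] = None,
) -> pd.DataFrame:
    """Full inversion chain: slopes -> (mu_a, mu_s') -> chromophores -> StO2.

    Returns a tissue-state table with one row per frame.  ``qc_pass`` is
    False for quality-gate rejections and for non-physical inversions;
    optical/chromophore columns hold NaN where undefined.  Rejection
    counts are attached as ``DataFrame.attrs``.
    """
    if fit is None:
        fit = fit_slopes(raw)
    qc = qc_gate(fit, r2_min)
    mua, mus = invert_optical_properties(fit.s_ac, fit.s_phi, config)
    physical = np.isfinite(mua).all(axis=-1) & np.isfinite(mus).all(axis=-1)
    n_nonphysical = int((~physical & qc).sum())
    if n_nonphysical:
        logger.warning("excluded %d frames with non-physical optical properties", n_nonphysical)
    ok = qc & physical

    c_hbo2 = np.full(raw.time_s.shape, np.nan)
    c_hhb = np.full(raw.time_s.shape, np.nan)
    sto2 = np.full(raw.time_s.shape, np.nan)
    if ok.any():
        cb, ch = unmix_chromophores(mua[ok, 0], mua[ok, 1], config)
        c_hbo2[ok], c_hhb[ok] = cb, ch
        total = cb + ch
        defined = total > 0
        vals = np.full(cb.shape, np.nan)
        vals[defined] = compute_sto2(cb[defined], ch[defined])
        sto2[ok] = vals

    wl_cols = {}
    for j, wl in enumerate(raw.wavelengths_nm):
        wl_cols[f"mua_{int(round(wl))}"] = np.where(ok, mua[:, j], np.nan)
        wl_cols[f"mus_{int(round(wl))}"] = np.where(ok, mus[:, j], np.nan)
    df = pd.DataFrame({"time_s": raw.time_s, **wl_cols, "c_hbo2": c_hbo2, "c_hhb": c_hhb,
                       "sto2": sto2, "qc_pass": ok})
    df.attrs["n_frames"] = int(raw.time_s.size)
    df.attrs["n_qc_rejected"] = int((~qc).sum())
    df.attrs["n_nonphysical"] = n_nonphysical
    return df
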