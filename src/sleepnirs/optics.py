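"""Photon-diffusion optics for frequency-domain multidistance NIRS.

The semi-infinite-medium diffusion model predicts that, versus
source-detector distance ``r``, the quantities ``ln(r^2 I_AC)``,
``ln(r^2 I_DC)`` and the phase delay ``phi`` are straight lines.  The
slopes of those lines carry the tissue's absorption coefficient ``mu_a``
and reduced scattering coefficient ``mu_s'``:

    mu_a  = omega / (2 v) * (S_phi / S_AC - S_AC / S_phi)
    mu_s' = (S_AC**2 - S_phi**2) / (3 mu_a) - mu_a

with ``omega`` the angular modulation frequency and ``v = c / n`` the
speed of light in tissue.  This module provides that inversion, its exact
analytic forward counterpart (the slope values the model predicts for a
given ``(mu_a, mu_s')``), the two-wavelength chromophore unmixing, and the
tissue-saturation definition ``StO2 = 100 * C_HbO2 / (C_HbO2 + C_HHb)``.

All lengths are centimetres, concentrations micromolar, and extinction
coefficients 1/(uM*cm) in the natural-log (mu_a) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, SingularInversionError, ValidationError

__all__ = [
    "SPEED_OF_LIGHT_CM_S",
    "DEFAULT_EXTINCTION",
    "OpticalConfig",
    "forward_slopes",
    "invert_optical_properties",
    "mua_from_chromophores",
    "unmix_chromophores",
    "compute_sto2",
    "chromophores_from_saturation",
]

SPEED_OF_LIGHT_CM_S = 2.99792458e10

_LN10 = math.log(10.0)

# Hemoglobin molar extinction coefficients, from the widely used Prahl
# compilation of Gratzer's spectra (tabulated there in 1/(cm*M), decadic).
# Converted here to the natural-log mu_a convention in 1/(uM*cm):
# eps = tabulated * ln(10) * 1e-6.  Overridable via OpticalConfig.
DEFAULT_EXTINCTION: Mapping[Tuple[str, float], float] = {
    ("HbO2", 690.0): 276.0 * _LN10 * 1e-6,
    ("HHb", 690.0): 2051.96 * _LN10 * 1e-6,
    ("HbO2", 830.0): 974.0 * _LN10 * 1e-6,
    ("HHb", 830.0): 693.04 * _LN10 * 1e-6,
}


@dataclass(frozen=True)
class OpticalConfig:
    """Instrument geometry, modulation and spectral constants.

    Defaults mirror a benchtop frequency-domain multidistance oximeter:
    two laser wavelengths (690 and 830 nm) modulated at 110 MHz, four
    source-detector separations (2, 2.5, 3, 3.5 cm), tissue refractive
    index 1.4, and a 5.2 Hz sampling rate.
    """

    wavelengths_nm: Tuple[float, ...] = (690.0, 830.0)
    distances_cm: Tuple[float, ...] = (2.0, 2.5, 3.0, 3.5)
    modulation_frequency_hz: float = 110e6
    refractive_index: float = 1.4
    extinction: Mapping[Tuple[str, float], float] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    sampling_rate_hz: float = 5.2
    # reduced scattering held fixed per wavelength during simulation
    mus_prime_cm: Mapping[float, float] = field(
        default_factory=lambda: {690.0: 9.0, 830.0: 8.0}
    )
    # regression intercepts used by the forward model (detector gain/offset)
    intercept_ac: float = 18.0
    intercept_dc: float = 19.0
    intercept_phase_rad: float = 0.3
    det_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_cm, dtype=float)
        if d.size < 3:
            raise ConfigurationError(
                "at least 3 source-detector distances are required for a "
                f"meaningful linear fit, got {d.size}"
            )
        if not np.all(np.diff(d) > 0):
            raise ConfigurationError("distances_cm must be strictly increasing")
        if len(self.wavelengths_nm) != 2:
            raise ConfigurationError(
                f"two wavelengths are required for unmixing, got {len(self.wavelengths_nm)}"
            )
        if not (self.modulation_frequency_hz > 0):
            raise ConfigurationError("modulation_frequency_hz must be positive")
        if not (self.refractive_index >= 1):
            raise ConfigurationError("refractive_index must be >= 1")
        if not (self.sampling_rate_hz > 0):
            raise ConfigurationError("sampling_rate_hz must be positive")
        for key in self._eps_keys():
            eps = self.extinction.get(key)
            if eps is None:
                raise ConfigurationError(f"missing extinction coefficient for {key}")
            if not (eps > 0):
                raise ConfigurationError(f"extinction coefficient {key} must be > 0")
        if abs(self._det()) <= self.det_tolerance:
            raise ConfigurationError(
                "extinction matrix is singular: wavelength pair cannot separate "
                "HbO2 from HHb"
            )

    def _eps_keys(self):
        for wl in self.wavelengths_nm:
            yield ("HbO2", wl)
            yield ("HHb", wl)

    def eps(self, chromophore: str, wavelength_nm: float) -> float:
        return float(self.extinction[(chromophore, wavelength_nm)])

    def _det(self) -> float:
        l1, l2 = self.wavelengths_nm
        return self.eps("HbO2", l1) * self.eps("HHb", l2) - self.eps(
            "HbO2", l2
        ) * self.eps("HHb", l1)

    @property
    def omega_rad_s(self) -> float:
        return 2.0 * math.pi * self.modulation_frequency_hz

    @property
    def light_speed_tissue_cm_s(self) -> float:
        return SPEED_OF_LIGHT_CM_S / self.refractive_index

    def with_(self, **changes) -> "OpticalConfig":
        return replace(self, **changes)


def forward_slopes(mua, mus_prime, config: OpticalConfig):
    """Analytic multidistance slopes for a homogeneous semi-infinite medium.

    Returns ``(s_ac, s_dc, s_phi)`` in 1/cm (phase slope in rad/cm) such
    that the slope-based inversion recovers ``(mua, mus_prime)`` exactly.
    With ``Q = sqrt(1 + (omega/(v*mua))^2)``:

        s_ac  = -sqrt(3 mua (mua + mus') / 2 * (Q + 1))
        s_phi = +sqrt(3 mua (mua + mus') / 2 * (Q - 1))
        s_dc  = -sqrt(3 mua (mua + mus'))          (omega -> 0 limit)

    Accepts scalars or broadcastable arrays.
    """
    mua = np.asarray(mua, dtype=float)
    mus_prime = np.asarray(mus_prime, dtype=float)
    if np.any(mua <= 0) or np.any(mus_prime <= 0):
        raise ValidationError("forward_slopes requires mua > 0 and mus_prime > 0")
    v = config.light_speed_tissue_cm_s
    q = np.sqrt(1.0 + (config.omega_rad_s / (v * mua)) ** 2)
    half = 1.5 * mua * (mua + mus_prime)  # 3*mua*(mua+mus')/2
    s_ac = -np.sqrt(half * (q + 1.0))
    s_phi = np.sqrt(half * (q - 1.0))
    s_dc = -np.sqrt(2.0 * half)
    return s_ac, s_dc, s_phi


def invert_optical_properties(s_ac, s_phi, config: OpticalConfig):
    """Recover ``(mua, mus_prime)`` from the AC-amplitude and phase slopes.

    Uses the (S_AC, S_phi) slope pair.  Non-physical outputs (mua <= 0 or
    mus' <= 0) are returned as NaN so callers can exclude the sample the
    same way a quality-gate failure is excluded.
    """
    s_ac = np.asarray(s_ac, dtype=float)
    s_phi = np.asarray(s_phi, dtype=float)
    if np.any(s_ac == 0) or np.any(s_phi == 0):
        raise SingularInversionError("zero slope: cannot invert optical properties")
    v = config.light_speed_tissue_cm_s
    mua = config.omega_rad_s / (2.0 * v) * (s_phi / s_ac - s_ac / s_phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        mus = (s_ac**2 - s_phi**2) / (3.0 * mua) - mua
    bad = ~(np.asarray(mua) > 0) | ~(np.asarray(mus) > 0)
    if np.ndim(mua) == 0:
        if bad:
            return float("nan"), float("nan")
        return float(mua), float(mus)
    mua = np.where(bad, np.nan, mua)
    mus = np.where(bad, np.nan, mus)
    return mua, mus


def mua_from_chromophores(c_hbo2, c_hhb, config: OpticalConfig):
    """Absorption per wavelength from chromophore concentrations (uM).

    mu_a^lambda = eps_HHb^lambda * C_HHb + eps_HbO2^lambda * C_HbO2.
    Returns an array with a trailing wavelength axis.
    """
    c_hbo2 = np.asarray(c_hbo2, dtype=float)
    c_hhb = np.asarray(c_hhb, dtype=float)
    if np.any(c_hbo2 < 0) or np.any(c_hhb < 0):
        raise ValidationError("chromophore concentrations must be non-negative")
    out = np.stack(
        [
            config.eps("HHb", wl) * c_hhb + config.eps("HbO2", wl) * c_hbo2
            for wl in config.wavelengths_nm
        ],
        axis=-1,
    )
    return out


def unmix_chromophores(mua_l1, mua_l2, config: OpticalConfig):
    """Two-wavelength closed-form solve for (C_HbO2, C_HHb) in uM.

    C_HbO2 = (mua^l1 eps_HHb^l2 - mua^l2 eps_HHb^l1) / det
    C_HHb  = (mua^l2 eps_HbO2^l1 - mua^l1 eps_HbO2^l2) / det
    det    = eps_HbO2^l1 eps_HHb^l2 - eps_HbO2^l2 eps_HHb^l1
    """
    l1, l2 = config.wavelengths_nm
    det = config._det()
    if abs(det) <= config.det_tolerance:
        raise SingularInversionError("ill-conditioned unmixing: extinction determinant ~ 0")
    mua_l1 = np.asarray(mua_l1, dtype=float)
    mua_l2 = np.asarray(mua_l2, dtype=float)
    c_hbo2 = (mua_l1 * config.eps("HHb", l2) - mua_l2 * config.eps("HHb", l1)) / det
    c_hhb = (mua_l2 * config.eps("HbO2", l1) - mua_l1 * config.eps("HbO2", l2)) / det
    if np.ndim(c_hbo2) == 0:
        return float(c_hbo2), float(c_hhb)
    return c_hbo2, c_hhb


def compute_sto2(c_hbo2, c_hhb):
    """Tissue oxygen saturation StO2 = 100 * C_HbO2 / (C_HbO2 + C_HHb), in %."""
    c_hbo2 = np.asarray(c_hbo2, dtype=float)
    c_hhb = np.asarray(c_hhb, dtype=float)
    total = c_hbo2 + c_hhb
    if np.any(total <= 0):
        raise ValidationError("undefined saturation: total hemoglobin must be > 0")
    out = 100.0 * c_hbo2 / total
    if np.ndim(out) == 0:
        return float(out)
    return out


def chromophores_from_saturation(sto2, total_hb_um):
    """Invert the StO2 definition: split total hemoglobin into HbO2 / HHb."""
    sto2 = np.asarray(sto2, dtype=float)
    if np.any(sto2 < 0) or np.any(sto2 > 100):
        raise ValidationError("StO2 must lie in [0, 100] %")
    if not np.all(np.asarray(total_hb_um) > 0):
        raise ValidationError("total_hb_um must be > 0")
    c_hbo2 = sto2 / 100.0 * total_hb_um
    c_hhb = total_hb_um - c_hbo2
    if np.ndim(c_hbo2) == 0:
        return float(c_hbo2), float(c_hhb)
    return c_hbo2, c_hhb
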