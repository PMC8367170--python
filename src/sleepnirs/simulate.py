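"""Synthetic sleep-recording generator.

Produces physiologically structured ground truth (arterial, venous and
tissue oxygen saturation with scheduled hypopnea desaturation events) and
the corresponding raw frequency-domain multidistance optical signals, so
the whole analysis chain can be exercised without patient data.

The physiological core is the arterio-venous mixing model

    StO2(t) = a * SaO2(t) + b * SvO2(t),        a + b = 1,

with the a/b pair (the arterio-venous ratio, AVR) defaulting to 0.30/0.70
as adopted by commercial tissue oximeters.  Hypopnea events pull SaO2
down along a trapezoidal profile; the venous compartment follows with a
configurable transport delay and an attenuation gain ``kappa`` in [0, 1].
The fingertip SpO2 channel is SaO2 sampled on its own (slower) clock plus
sensor noise.

The optical forward model turns the StO2 ground truth into per-timepoint
multidistance AC/DC intensities and phases through the photon-diffusion
slope model (see :mod:`sleepnirs.optics`), adds instrument noise,
hemodynamic oscillations (cardiac / respiratory / slow waves expressed as
hemoglobin concentration ripples), and optional bad-contact segments that
break the across-distance linearity at one detector separation so the
downstream R^2 quality gate has something real to catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import HypopneaEvent
from .optics import OpticalConfig, chromophores_from_saturation, forward_slopes, mua_from_chromophores

__all__ = [
    "DesatDistribution",
    "PhysioParams",
    "PhysioTraces",
    "RawOpticalData",
    "BadContactSegment",
    "simulate_physiology",
    "synthesize_raw",
]


@dataclass(frozen=True)
class DesatDistribution:
    """Distribution of per-event fingertip desaturation magnitudes (%).

    Default is a lognormal truncated to [minimum_pct, maximum_pct] by
    rejection sampling, so the cap is a true truncation rather than a
    clip.  The default 15% cap mirrors the analysis rule that events with
    larger fingertip desaturations are excluded as unreliable; a larger
    cap may be configured to exercise that exclusion path.
    """

    kind: str = "lognormal"  # "lognormal" | "uniform" | "fixed"
    median_pct: float = 4.0
    sigma: float = 0.45
    minimum_pct: float = 1.0
    maximum_pct: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "uniform", "fixed"):
            raise ValidationError(f"desat_magnitude_dist.kind unknown: {self.kind!r}")
        if not (0 < self.minimum_pct <= self.maximum_pct):
            raise ValidationError(
                "desat_magnitude_dist: need 0 < minimum_pct <= maximum_pct, got "
                f"({self.minimum_pct}, {self.maximum_pct})"
            )
        if self.kind == "lognormal" and not (self.sigma >= 0 and self.median_pct > 0):
            raise ValidationError("desat_magnitude_dist: median_pct > 0 and sigma >= 0 required")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if self.kind == "fixed":
            return np.full(n, self.median_pct)
        if self.kind == "uniform":
            return rng.uniform(self.minimum_pct, self.maximum_pct, n)
        out = np.empty(n)
        filled = 0
        mu = math.log(self.median_pct)
        for _ in range(1000):
            draw = rng.lognormal(mu, self.sigma, 2 * (n - filled) + 8)
            keep = draw[(draw >= self.minimum_pct) & (draw <= self.maximum_pct)]
            take = min(keep.size, n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
            if filled == n:
                return out
        raise ValidationError(
            "desat_magnitude_dist: truncation bounds reject essentially all draws"
        )


@dataclass(frozen=True)
class PhysioParams:
    """Physiology, event schedule and noise settings for the generator.

    Saturations are percentages; concentrations micromolar; times seconds.
    ``avr_a``/``avr_b`` are the arterial/venous weights of the tissue
    saturation mixture and must sum to 1.  ``venous_attenuation_kappa`` is
    the fraction of the arterial desaturation transmitted to the venous
    compartment and ``venous_lag_s`` the transport delay of that response.
    """

    baseline_sao2: float = 96.0
    baseline_sto2: float = 68.8
    avr_a: float = 0.30
    avr_b: float = 0.70
    venous_attenuation_kappa: float = 0.5
    venous_lag_s: float = 10.0
    event_rate_per_hour: float = 20.0
    events_per_condition: Optional[Mapping[str, int]] = None
    event_duration_range_s: Tuple[float, float] = (30.0, 60.0)
    event_ramp_s: float = 8.0
    desat_magnitude_dist: DesatDistribution = field(default_factory=DesatDistribution)
    total_hb_um: float = 80.0
    # hemodynamic oscillations, expressed as hemoglobin-concentration ripples
    cardiac_amp_um: float = 0.3
    cardiac_freq_hz: float = 1.1
    resp_amp_um: float = 0.5
    resp_freq_hz: float = 0.25
    slow_amp_um: float = 0.8
    slow_freq_hz: float = 0.1
    # instrument noise on the raw optical channels
    intensity_noise_frac: float = 0.005
    phase_noise_rad: float = 0.002
    # fingertip oximeter channel
    spo2_rate_hz: float = 1.0
    spo2_noise_pct: float = 0.1
    # probe-contact artefacts
    bad_contact_rate_per_hour: float = 1.0
    bad_contact_duration_s: float = 5.0
    bad_contact_ln_amp_offset: float = 1.0
    bad_contact_phase_offset_rad: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        def chk(name: str, cond: bool) -> None:
            if not cond:
                raise ValidationError(f"PhysioParams.{name} is out of range or non-finite")

        for name in (
            "baseline_sao2",
            "baseline_sto2",
            "avr_a",
            "avr_b",
            "venous_attenuation_kappa",
            "venous_lag_s",
            "event_rate_per_hour",
            "event_ramp_s",
            "total_hb_um",
            "cardiac_amp_um",
            "resp_amp_um",
            "slow_amp_um",
            "intensity_noise_frac",
            "phase_noise_rad",
            "spo2_rate_hz",
            "spo2_noise_pct",
            "bad_contact_rate_per_hour",
            "bad_contact_duration_s",
        ):
            chk(name, math.isfinite(float(getattr(self, name))))
        chk("baseline_sao2", 0 <= self.baseline_sao2 <= 100)
        chk("baseline_sto2", 0 <= self.baseline_sto2 <= 100)
        chk("avr_a", 0 <= self.avr_a <= 1)
        chk("avr_b", 0 <= self.avr_b <= 1)
        if abs(self.avr_a + self.avr_b - 1.0) > 1e-9:
            raise ValidationError("PhysioParams.avr_a + avr_b must equal 1")
        chk("venous_attenuation_kappa", 0 <= self.venous_attenuation_kappa <= 1)
        chk("venous_lag_s", self.venous_lag_s >= 0)
        chk("event_rate_per_hour", self.event_rate_per_hour >= 0)
        lo, hi = self.event_duration_range_s
        if not (10.0 <= lo <= hi):
            raise ValidationError(
                "PhysioParams.event_duration_range_s: hypopneas last at least 10 s "
                f"and lo <= hi is required, got ({lo}, {hi})"
            )
        chk("event_ramp_s", self.event_ramp_s > 0)
        chk("total_hb_um", self.total_hb_um > 0)
        chk("spo2_rate_hz", self.spo2_rate_hz > 0)
        for name in (
            "cardiac_amp_um",
            "resp_amp_um",
            "slow_amp_um",
            "intensity_noise_frac",
            "phase_noise_rad",
            "spo2_noise_pct",
            "bad_contact_rate_per_hour",
            "bad_contact_duration_s",
        ):
            chk(name, getattr(self, name) >= 0)

    @property
    def noiseless(self) -> bool:
        return (
            self.cardiac_amp_um == 0
            and self.resp_amp_um == 0
            and self.slow_amp_um == 0
            and self.intensity_noise_frac == 0
            and self.phase_noise_rad == 0
            and self.spo2_noise_pct == 0
        )

    def with_(self, **changes) -> "PhysioParams":
        return replace(self, **changes)

    def without_noise(self) -> "PhysioParams":
        return self.with_(
            cardiac_amp_um=0.0,
            resp_amp_um=0.0,
            slow_amp_um=0.0,
            intensity_noise_frac=0.0,
            phase_noise_rad=0.0,
            spo2_noise_pct=0.0,
            bad_contact_rate_per_hour=0.0,
        )

    def venous_baseline(self) -> float:
        """Baseline SvO2 consistent with the configured StO2 mixture."""
        if self.avr_b == 0:
            return self.baseline_sao2
        sv = (self.baseline_sto2 - self.avr_a * self.baseline_sao2) / self.avr_b
        if not (0 <= sv <= 100):
            raise ValidationError(
                "PhysioParams.baseline_sto2 inconsistent with avr weights: implied "
                f"baseline SvO2 = {sv:.2f}% is outside [0, 100]"
            )
        return sv


@dataclass
class PhysioTraces:
    """Ground-truth physiological traces on the tissue-oximeter clock."""

    time_s: np.ndarray
    sao2: np.ndarray
    svo2: np.ndarray
    sto2: np.ndarray
    spo2_time_s: np.ndarray
    spo2_pct: np.ndarray
    events: List[HypopneaEvent]
    event_magnitudes: Mapping[str, float]
    conditions: Tuple[str, ...]
    duration_s: float
    params: PhysioParams

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def ground_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "sao2": self.sao2, "svo2": self.svo2, "sto2": self.sto2}
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": [e.event_id for e in self.events],
                "type": ["hypopnea"] * len(self.events),
                "condition": [e.condition for e in self.events],
                "start_s": [e.start_s for e in self.events],
                "end_s": [e.end_s for e in self.events],
            }
        )

    def spo2_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.spo2_time_s, "spo2_pct": self.spo2_pct})


@dataclass
class BadContactSegment:
    """Interval during which one detector separation loses good skin contact."""

    start_s: float
    end_s: float
    distance_cm: float


@dataclass
class RawOpticalData:
    """Raw multidistance frequency-domain optical series.

    ``i_dc``, ``i_ac`` and ``phase_rad`` have shape (n_times, n_wavelengths,
    n_distances); intensities are in arbitrary detector units.
    """

    time_s: np.ndarray
    wavelengths_nm: np.ndarray
    distances_cm: np.ndarray
    i_dc: np.ndarray
    i_ac: np.ndarray
    phase_rad: np.ndarray

    def to_long(self) -> pd.DataFrame:
        n_t, n_wl, n_d = self.i_ac.shape
        t = np.repeat(self.time_s, n_wl * n_d)
        wl = np.tile(np.repeat(self.wavelengths_nm, n_d), n_t)
        r = np.tile(self.distances_cm, n_t * n_wl)
        return pd.DataFrame(
            {
                "time_s": t,
                "wavelength_nm": wl,
                "distance_cm": r,
                "i_dc": self.i_dc.reshape(-1),
                "i_ac": self.i_ac.reshape(-1),
                "phase_rad": self.phase_rad.reshape(-1),
            }
        )

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "RawOpticalData":
        required = {"time_s", "wavelength_nm", "distance_cm", "i_dc", "i_ac", "phase_rad"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"raw optical table missing columns: {sorted(missing)}")
        times = np.unique(frame["time_s"].to_numpy())
        wls = np.unique(frame["wavelength_nm"].to_numpy())
        dists = np.unique(frame["distance_cm"].to_numpy())
        shape = (times.size, wls.size, dists.size)
        if len(frame) != times.size * wls.size * dists.size:
            raise ValidationError(
                "raw optical table is not a complete time x wavelength x distance grid"
            )
        ordered = frame.sort_values(["time_s", "wavelength_nm", "distance_cm"], kind="mergesort")
        return cls(
            time_s=times,
            wavelengths_nm=wls,
            distances_cm=dists,
            i_dc=ordered["i_dc"].to_numpy().reshape(shape),
            i_ac=ordered["i_ac"].to_numpy().reshape(shape),
            phase_rad=ordered["phase_rad"].to_numpy().reshape(shape),
        )


def _resolve_rng(rng: Optional[np.random.Generator], seed: Optional[int], default_seed: int):
    if rng is not None:
        return rng
    return np.random.default_rng(default_seed if seed is None else seed)


def _schedule_events(
    params: PhysioParams,
    duration_s: float,
    conditions: Sequence[str],
    rng: np.random.Generator,
) -> Tuple[List[HypopneaEvent], dict]:
    """Place non-overlapping events with guard margins inside each condition segment."""
    margin_pre = 45.0  # room for the pre-event baseline window
    margin_post = 50.0  # recovery + nadir search extension
    n_cond = len(conditions)
    seg_len = duration_s / n_cond
    events: List[HypopneaEvent] = []
    magnitudes: dict = {}
    counter = 0
    for ci, label in enumerate(conditions):
        seg_start = ci * seg_len
        if params.events_per_condition is not None:
            n = int(params.events_per_condition.get(label, 0))
        else:
            n = int(round(params.event_rate_per_hour * seg_len / 3600.0))
        if n == 0:
            continue
        lo, hi = params.event_duration_range_s
        durations = rng.uniform(lo, hi, n)
        mags = params.desat_magnitude_dist.sample(rng, n)
        cells = margin_pre + durations + margin_post
        slack = seg_len - cells.sum()
        if slack < 0:
            raise ValidationError(
                f"PhysioParams.event_rate_per_hour: {n} events do not fit in the "
                f"{seg_len:.0f} s segment for condition {label!r}"
            )
        gaps = slack * rng.dirichlet(np.ones(n + 1))
        cursor = seg_start
        for i in range(n):
            cursor += gaps[i] + margin_pre
            start = cursor
            end = start + durations[i]
            cursor = end + margin_post
            eid = f"ev{counter:04d}"
            counter += 1
            events.append(HypopneaEvent(event_id=eid, condition=label, start_s=start, end_s=end))
            magnitudes[eid] = float(mags[i])
    return events, magnitudes


def _sao2_evaluator(
    params: PhysioParams, events: Sequence[HypopneaEvent], magnitudes: Mapping[str, float]
) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous-time SaO2(t): baseline minus trapezoidal event dips."""

    def sao2_of(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, params.baseline_sao2)
        # t is a sorted clock, so each event touches one contiguous slice
        for ev in events:
            dur = ev.end_s - ev.start_s
            ramp = min(params.event_ramp_s, dur / 3.0)
            lo = int(np.searchsorted(t, ev.start_s, side="left"))
            hi = int(np.searchsorted(t, ev.end_s, side="right"))
            if hi <= lo:
                continue
            u = t[lo:hi] - ev.start_s
            depth = np.clip(np.minimum(u / ramp, (dur - u) / ramp), 0.0, 1.0)
            out[lo:hi] -= magnitudes[ev.event_id] * depth
        return out

    return sao2_of


def simulate_physiology(
    params: PhysioParams,
    duration_s: float,
    conditions: Sequence[str] = ("baseline",),
    sampling_rate_hz: float = 5.2,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> PhysioTraces:
    """Generate saturation ground truth plus event annotations.

    ``duration_s`` is the total recording length, split evenly across the
    given condition labels in order (mirroring a baseline hour followed by
    stepwise CPAP pressure hours).  The venous trace follows the arterial
    deviation with gain ``kappa`` and a pure transport delay, so that with
    zero noise the mixture identity and the per-event attenuation factor
    ``avr_a + avr_b * kappa`` hold exactly.
    """
    if not (duration_s > 0):
        raise ValidationError("duration_s must be positive")
    if len(conditions) == 0:
        raise ValidationError("at least one condition label is required")
    rng = _resolve_rng(rng, seed, params.rng_seed)

    events, magnitudes = _schedule_events(params, duration_s, conditions, rng)
    sao2_of = _sao2_evaluator(params, events, magnitudes)

    n = int(math.floor(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    sao2 = sao2_of(t)
    sv_base = params.venous_baseline()
    dev_lagged = params.baseline_sao2 - sao2_of(t - params.venous_lag_s)
    svo2 = sv_base - params.venous_attenuation_kappa * dev_lagged
    sto2 = params.avr_a * sao2 + params.avr_b * svo2

    t_sp = np.arange(int(math.floor(duration_s * params.spo2_rate_hz))) / params.spo2_rate_hz
    spo2 = sao2_of(t_sp)
    if params.spo2_noise_pct > 0:
        spo2 = spo2 + params.spo2_noise_pct * rng.standard_normal(t_sp.size)
    spo2 = np.clip(spo2, 0.0, 100.0)

    return PhysioTraces(
        time_s=t,
        sao2=sao2,
        svo2=svo2,
        sto2=sto2,
        spo2_time_s=t_sp,
        spo2_pct=spo2,
        events=events,
        event_magnitudes=magnitudes,
        conditions=tuple(conditions),
        duration_s=duration_s,
        params=params,
    )


def synthesize_raw(
    traces: PhysioTraces,
    config: OpticalConfig,
    params: Optional[PhysioParams] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[RawOpticalData, List[BadContactSegment]]:
    """Forward-model raw optical frames from the StO2 ground truth.

    Per timepoint and wavelength the tissue absorption follows from the
    mixed-state chromophore concentrations; reduced scattering is held at
    the configured per-wavelength constant.  The analytic diffusion slopes
    then yield, per distance r,

        I_AC(r) = exp(C_AC + r S_AC) / r^2     (and likewise for I_DC)
        phi(r)  = C_phi + r S_phi

    before multiplicative intensity noise, additive phase jitter and the
    scheduled bad-contact perturbations are applied.
    """
    params = traces.params if params is None else params
    rng = _resolve_rng(rng, seed, params.rng_seed + 1)

    fs = traces.sampling_rate_hz
    if abs(fs - config.sampling_rate_hz) > 1e-9:
        raise ValidationError(
            "mismatched clocks: traces sampled at "
            f"{fs} Hz but optical config expects {config.sampling_rate_hz} Hz"
        )

    c_hbo2, c_hhb = chromophores_from_saturation(traces.sto2, params.total_hb_um)
    c_hbo2 = np.asarray(c_hbo2, dtype=float).copy()
    c_hhb = np.asarray(c_hhb, dtype=float).copy()

    # hemodynamic oscillations: cardiac ripple is almost purely arterial
    # (oxygenated); respiratory and slow waves move mixed blood volume
    t = traces.time_s
    for amp, freq, oxy_frac in (
        (params.cardiac_amp_um, params.cardiac_freq_hz, 0.98),
        (params.resp_amp_um, params.resp_freq_hz, 0.7),
        (params.slow_amp_um, params.slow_freq_hz, 0.7),
    ):
        if amp > 0:
            wave = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            c_hbo2 += oxy_frac * wave
            c_hhb += (1 - oxy_frac) * wave
    np.clip(c_hbo2, 1e-6, None, out=c_hbo2)
    np.clip(c_hhb, 1e-6, None, out=c_hhb)

    mua = mua_from_chromophores(c_hbo2, c_hhb, config)  # (n_t, n_wl)
    mus = np.array([config.mus_prime_cm[wl] for wl in config.wavelengths_nm])
    s_ac, s_dc, s_phi = forward_slopes(mua, mus[np.newaxis, :], config)

    r = np.asarray(config.distances_cm)
    i_ac = np.exp(config.intercept_ac + r * s_ac[..., np.newaxis]) / r**2
    i_dc = np.exp(config.intercept_dc + r * s_dc[..., np.newaxis]) / r**2
    phase = config.intercept_phase_rad + r * s_phi[..., np.newaxis]

    if params.intensity_noise_frac > 0:
        i_ac = i_ac * np.exp(params.intensity_noise_frac * rng.standard_normal(i_ac.shape))
        i_dc = i_dc * np.exp(params.intensity_noise_frac * rng.standard_normal(i_dc.shape))
    if params.phase_noise_rad > 0:
        phase = phase + params.phase_noise_rad * rng.standard_normal(phase.shape)

    segments: List[BadContactSegment] = []
    n_seg = int(round(params.bad_contact_rate_per_hour * traces.duration_s / 3600.0))
    if n_seg > 0 and params.bad_contact_duration_s > 0:
        far = float(r[-1])
        starts = rng.uniform(0, traces.duration_s - params.bad_contact_duration_s, n_seg)
        for s0 in np.sort(starts):
            s1 = s0 + params.bad_contact_duration_s
            mask = (t >= s0) & (t < s1)
            i_ac[mask, :, -1] *= math.exp(-params.bad_contact_ln_amp_offset)
            i_dc[mask, :, -1] *= math.exp(-params.bad_contact_ln_amp_offset)
            phase[mask, :, -1] += params.bad_contact_phase_offset_rad
            segments.append(BadContactSegment(start_s=float(s0), end_s=float(s1), distance_cm=far))

    raw = RawOpticalData(
        time_s=t,
        wavelengths_nm=np.asarray(config.wavelengths_nm, dtype=float),
        distances_cm=np.asarray(r, dtype=float),
        i_dc=i_dc,
        i_ac=i_ac,
        phase_rad=phase,
    )
    return raw, segments


def bad_contact_sample_mask(
    time_s: np.ndarray, segments: Sequence[BadContactSegment]
) -> np.ndarray:
    """Boolean mask of samples falling inside any bad-contact segment."""
    mask = np.zeros(time_s.shape, dtype=bool)
    for seg in segments:
        mask |= (time_s >= seg.start_s) & (time_s < seg.end_s)
    return mask
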