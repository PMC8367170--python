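"""Per-event oxygen desaturation extraction and exclusion bookkeeping.

For every annotated hypopnea the desaturation (OD) on a channel is the
pre-event baseline level minus the nadir reached during the event window
(extended past the annotated end, since the saturation nadir lags the
airflow recovery), floored at zero.  The fingertip OD comes from the SpO2
trace, the arm OD from the processed tissue-saturation trace; the two are
paired strictly by event id.  Events whose fingertip desaturation exceeds
15% are excluded from all statistics but retained in the ledger, and the
arm OD is additionally expressed relative to its pre-event StO2 baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError

__all__ = [
    "MIN_HYPOPNEA_DURATION_S",
    "HypopneaEvent",
    "extract_event_od",
    "normalize_arm_od",
    "apply_exclusion",
    "compute_event_table",
]

MIN_HYPOPNEA_DURATION_S = 10.0


@dataclass(frozen=True)
class HypopneaEvent:
    """An annotated hypopnea: scored externally, consumed here as given."""

    event_id: str
    condition: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValidationError(f"event {self.event_id}: non-finite start/end")
        if self.end_s - self.start_s < MIN_HYPOPNEA_DURATION_S:
            raise ValidationError(
                f"event {self.event_id}: duration {self.end_s - self.start_s:.2f} s "
                f"is below the {MIN_HYPOPNEA_DURATION_S:.0f} s hypopnea minimum"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _window_indices(series, t_lo: float, t_hi: float, closed_right: bool) -> np.ndarray:
    """Indices of samples with time in [t_lo, t_hi) or [t_lo, t_hi]."""
    fs = series.sampling_rate_hz
    i_lo = int(math.ceil((t_lo - series.start_time_s) * fs - 1e-9))
    edge = (t_hi - series.start_time_s) * fs
    i_hi = int(math.floor(edge + 1e-9)) if closed_right else int(math.ceil(edge - 1e-9)) - 1
    i_lo = max(i_lo, 0)
    i_hi = min(i_hi, len(series.values) - 1)
    if i_hi < i_lo:
        return np.empty(0, dtype=int)
    return np.arange(i_lo, i_hi + 1)


def extract_event_od(
    trace,
    event: HypopneaEvent,
    baseline_window_s: float = 30.0,
    search_extension_s: float = 30.0,
    max_gap_fraction: float = 0.25,
) -> Tuple[float, float]:
    """Return ``(od, baseline_value)`` for one event on one channel.

    ``baseline_value`` is the mean of the trace over the
    ``baseline_window_s`` seconds preceding the event start; the nadir is
    searched from the event start to ``search_extension_s`` past the event
    end; ``od = max(0, baseline - nadir)``.  Gap-masked samples are
    excluded from both windows; the event is refused (``CoverageError``)
    when the trace does not cover the required span, when the baseline
    window is entirely masked, or when more than ``max_gap_fraction`` of
    the search window is masked (the nadir could be hiding in the gap).
    """
    t0 = event.start_s - baseline_window_s
    t1 = event.end_s + search_extension_s
    eps = 0.5 / trace.sampling_rate_hz
    if t0 < trace.start_time_s - eps or t1 > trace.end_time_s + eps:
        raise CoverageError(
            f"event {event.event_id}: trace covers [{trace.start_time_s:.1f}, "
            f"{trace.end_time_s:.1f}] s but [{t0:.1f}, {t1:.1f}] s is required"
        )
    base_idx = _window_indices(trace, t0, event.start_s, closed_right=False)
    win_idx = _window_indices(trace, event.start_s, t1, closed_right=True)
    base_ok = base_idx[~trace.gap_mask[base_idx]]
    win_ok = win_idx[~trace.gap_mask[win_idx]]
    if base_ok.size == 0:
        raise CoverageError(f"event {event.event_id}: baseline window entirely gap-masked")
    if win_idx.size == 0 or win_ok.size < (1 - max_gap_fraction) * win_idx.size:
        raise CoverageError(
            f"event {event.event_id}: more than {max_gap_fraction:.0%} of the "
            "nadir search window is gap-masked"
        )
    baseline = float(np.mean(trace.values[base_ok]))
    nadir = float(np.min(trace.values[win_ok]))
    return max(0.0, baseline - nadir), baseline


def normalize_arm_od(arm_od: float, baseline_sto2: float) -> float:
    """Express the arm desaturation as percent of its pre-event StO2 level."""
    if not (baseline_sto2 > 0):
        raise ValidationError(
            f"undefined normalization: baseline StO2 must be > 0, got {baseline_sto2}"
        )
    return 100.0 * arm_od / baseline_sto2


def apply_exclusion(table: pd.DataFrame, max_finger_od: float = 15.0) -> pd.DataFrame:
    """Mark events whose fingertip desaturation exceeds the cap as excluded.

    The rule is strictly greater-than: an event at exactly the cap is
    retained.  Excluded events stay in the table (the exclusion ledger)
    but carry ``excluded=True`` so downstream statistics drop them.
    """
    out = table.copy()
    mask = out["finger_od"] > max_finger_od
    out["excluded"] = mask
    out["exclude_reason"] = np.where(mask, f"finger_od>{max_finger_od:g}%", "")
    return out


def compute_event_table(
    arm_trace,
    spo2_trace,
    events: Sequence[HypopneaEvent],
    baseline_window_s: float = 30.0,
    search_extension_s: float = 30.0,
    max_finger_od: float = 15.0,
) -> Tuple[pd.DataFrame, List[str]]:
    """Pair finger and arm desaturations per event and apply the exclusion rule.

    Returns the per-event table and a log of skipped events (insufficient
    trace coverage on either channel).  Channels are paired by event id,
    never by timestamp matching.
    """
    rows = []
    skipped: List[str] = []
    for ev in events:
        try:
            finger_od, _ = extract_event_od(
                spo2_trace, ev, baseline_window_s, search_extension_s
            )
            arm_od, base_sto2 = extract_event_od(
                arm_trace, ev, baseline_window_s, search_extension_s
            )
        except CoverageError as exc:
            skipped.append(str(exc))
            continue
        rows.append(
            {
                "event_id": ev.event_id,
                "condition": ev.condition,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "finger_od": finger_od,
                "arm_od": arm_od,
                "arm_od_norm": normalize_arm_od(arm_od, base_sto2),
                "baseline_sto2": base_sto2,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "condition",
            "start_s",
            "end_s",
            "finger_od",
            "arm_od",
            "arm_od_norm",
            "baseline_sto2",
        ],
    )
    return apply_exclusion(table, max_finger_od), skipped
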