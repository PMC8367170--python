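"""Per-event desaturation extraction, exclusion rule and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepnirs import (
    HypopneaEvent,
    PhysioParams,
    UniformSeries,
    apply_exclusion,
    compute_event_table,
    extract_event_od,
    normalize_arm_od,
    simulate_physiology,
)
from sleepnirs.errors import CoverageError, ValidationError
from sleepnirs.simulate import DesatDistribution


def _series(values, fs=1.0, gap=None):
    return UniformSeries(0.0, fs, np.asarray(values, dtype=float), gap)


def _event(start=100.0, end=130.0, cond="baseline", eid="e1"):
    return HypopneaEvent(event_id=eid, condition=cond, start_s=start, end_s=end)


class TestExtract:
    def test_flat_trace_gives_zero(self):
        od, base = extract_event_od(_series(np.full(300, 95.0)), _event())
        assert od == 0.0
        assert base == pytest.approx(95.0)

    def test_step_down_inside_event(self):
        x = np.full(300, 95.0)
        x[105:125] = 91.0
        od, base = extract_event_od(_series(x), _event())
        assert od == pytest.approx(4.0)

    def test_nadir_in_search_extension_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = 95.0 + 0.1 * rng.standard_normal(300)
        x[145] = 89.0  # nadir 15 s after event end
        ev = _event()
        od, base = extract_event_od(_series(x), ev, search_extension_s=30.0)
        window = x[100:161]  # [start, end+ext] inclusive at 1 Hz
        assert od == pytest.approx(max(0.0, x[70:100].mean() - window.min()), abs=1e-12)

    def test_od_floored_at_zero(self):
        x = np.full(300, 95.0)
        x[100:160] = 97.0  # trace rises during the event
        od, _ = extract_event_od(_series(x), _event())
        assert od == 0.0

    def test_insufficient_coverage_raises(self):
        with pytest.raises(CoverageError):
            extract_event_od(_series(np.full(120, 95.0)), _event())

    def test_fully_masked_baseline_raises(self):
        gap = np.zeros(300, dtype=bool)
        gap[70:100] = True
        with pytest.raises(CoverageError):
            extract_event_od(_series(np.full(300, 95.0), gap=gap), _event())


class TestExclusion:
    def _table(self, finger_ods):
        return pd.DataFrame(
            {
                "event_id": [f"e{i}" for i in range(len(finger_ods))],
                "condition": "baseline",
                "finger_od": finger_ods,
                "arm_od": [1.0] * len(finger_ods),
                "arm_od_norm": [1.5] * len(finger_ods),
                "baseline_sto2": [68.0] * len(finger_ods),
            }
        )

    def test_above_cap_excluded(self):
        out = apply_exclusion(self._table([16.0, 4.0]))
        assert out["excluded"].tolist() == [True, False]
        assert out["exclude_reason"].iloc[0] == "finger_od>15%"

    def test_exactly_at_cap_retained(self):
        out = apply_exclusion(self._table([15.0]))
        assert not out["excluded"].any()

    def test_no_event_above_cap_is_identity(self):
        table = self._table([2.0, 5.0, 14.9])
        out = apply_exclusion(table)
        assert not out["excluded"].any()
        pd.testing.assert_frame_equal(out.drop(columns=["excluded", "exclude_reason"]), table)


class TestNormalization:
    @pytest.mark.parametrize(
        "arm_od,base,expected", [(0.0, 50.0, 0.0), (1.5, 50.0, 3.0), (2.0, 68.8, 2.907)]
    )
    def test_arithmetic(self, arm_od, base, expected):
        assert normalize_arm_od(arm_od, base) == pytest.approx(expected, abs=5e-4)

    def test_undefined_for_nonpositive_baseline(self):
        with pytest.raises(ValidationError):
            normalize_arm_od(1.0, 0.0)

    @given(
        od1=st.floats(0.0, 10.0),
        delta=st.floats(0.1, 5.0),
        base=st.floats(30.0, 90.0),
        dbase=st.floats(0.5, 20.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_both_arguments(self, od1, delta, base, dbase):
        assert normalize_arm_od(od1 + delta, base) > normalize_arm_od(od1, base)
        if od1 > 0:
            assert normalize_arm_od(od1, base + dbase) < normalize_arm_od(od1, base)


class TestPairing:
    def _traces(self, params, duration=2000.0):
        tr = simulate_physiology(params, duration, ("baseline",), seed=21)
        arm = UniformSeries(0.0, tr.sampling_rate_hz, tr.sto2)
        spo2 = UniformSeries(0.0, 1.0, tr.spo2_pct)
        return tr, arm, spo2

    def test_pure_arterial_channels_agree(self):
        params = PhysioParams(
            avr_a=1.0, avr_b=0.0, venous_lag_s=0.0, events_per_condition={"baseline": 4}
        ).without_noise()
        tr, arm, spo2 = self._traces(params)
        table, skipped = compute_event_table(arm, spo2, tr.events)
        assert not skipped
        assert len(table) == 4
        assert np.max(np.abs(table["finger_od"] - table["arm_od"])) <= 0.1

    def test_mixing_ratio_per_event(self):
        params = PhysioParams(
            venous_lag_s=0.0, events_per_condition={"baseline": 5}
        ).without_noise()
        tr, arm, spo2 = self._traces(params)
        table, _ = compute_event_table(arm, spo2, tr.events)
        expected = params.avr_a + params.avr_b * params.venous_attenuation_kappa
        ratio = table["arm_od"] / table["finger_od"]
        assert np.max(np.abs(ratio / expected - 1)) <= 0.02

    def test_pairing_is_by_event_id(self):
        params = PhysioParams(events_per_condition={"baseline": 3}).without_noise()
        tr, arm, spo2 = self._traces(params)
        table, _ = compute_event_table(arm, spo2, tr.events)
        assert table["event_id"].tolist() == [ev.event_id for ev in tr.events]

    def test_event_overlapping_large_gap_is_skipped(self):
        params = PhysioParams(events_per_condition={"baseline": 2}).without_noise()
        tr, arm, spo2 = self._traces(params)
        ev = tr.events[0]
        lo = int(ev.start_s * arm.sampling_rate_hz)
        hi = int(ev.end_s * arm.sampling_rate_hz)
        arm.gap_mask[lo:hi] = True
        table, skipped = compute_event_table(arm, spo2, tr.events)
        assert len(table) == 1
        assert len(skipped) == 1 and ev.event_id in skipped[0]


def test_hypopnea_minimum_duration_enforced():
    with pytest.raises(ValidationError):
        HypopneaEvent(event_id="x", condition="baseline", start_s=0.0, end_s=9.0)
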