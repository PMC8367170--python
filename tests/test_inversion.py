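"""Slope regression, quality gate and the full tissue-oximetry inversion chain."""

import numpy as np
import pytest

from sleepnirs import OpticalConfig, PhysioParams, simulate_physiology, synthesize_raw
from sleepnirs.errors import ConfigurationError, DataError
from sleepnirs.inversion import SlopeFitSeries, fit_slopes, process_raw, qc_gate
from sleepnirs.simulate import DesatDistribution, RawOpticalData


def _frame(r, i_dc, i_ac, phase):
    """Single-timepoint raw container with one wavelength."""
    shape = (1, 1, len(r))
    return RawOpticalData(
        time_s=np.array([0.0]),
        wavelengths_nm=np.array([690.0]),
        distances_cm=np.asarray(r, dtype=float),
        i_dc=np.asarray(i_dc, dtype=float).reshape(shape),
        i_ac=np.asarray(i_ac, dtype=float).reshape(shape),
        phase_rad=np.asarray(phase, dtype=float).reshape(shape),
    )


class TestFitSlopes:
    def test_exact_linear_inputs_recovered(self):
        r = np.array([2.0, 2.5, 3.0, 3.5])
        s_ac, c_ac = -1.8, 10.0
        s_dc, c_dc = -1.7, 11.0
        s_phi, c_phi = 0.28, 0.0
        frame = _frame(
            r,
            np.exp(c_dc + r * s_dc) / r**2,
            np.exp(c_ac + r * s_ac) / r**2,
            c_phi + r * s_phi,
        )
        fit = fit_slopes(frame)
        assert fit.s_ac[0, 0] == pytest.approx(s_ac, rel=1e-12)
        assert fit.c_ac[0, 0] == pytest.approx(c_ac, rel=1e-12)
        assert fit.s_dc[0, 0] == pytest.approx(s_dc, rel=1e-12)
        assert fit.s_phi[0, 0] == pytest.approx(s_phi, rel=1e-12)
        assert fit.r2_ac[0, 0] == pytest.approx(1.0)
        assert fit.r2_phi[0, 0] == pytest.approx(1.0)

    def test_hand_least_squares_phase_example(self):
        r = np.array([2.0, 2.5, 3.0, 3.5])
        frame = _frame(r, np.ones(4), np.ones(4), [0.56, 0.70, 0.84, 0.98])
        fit = fit_slopes(frame)
        assert fit.s_phi[0, 0] == pytest.approx(0.28, rel=1e-12)
        assert fit.c_phi[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_phase_gives_zero_slope(self):
        r = np.array([2.0, 2.5, 3.0, 3.5])
        frame = _frame(r, np.ones(4), np.ones(4), np.full(4, 0.4))
        fit = fit_slopes(frame)
        assert fit.s_phi[0, 0] == 0.0
        assert fit.r2_phi[0, 0] == 1.0  # zero residual: perfect (flat) fit

    def test_nonpositive_intensity_identified(self):
        r = np.array([2.0, 2.5, 3.0, 3.5])
        i_ac = np.array([1.0, 1.0, -1.0, 1.0])
        frame = _frame(r, np.ones(4), i_ac, np.zeros(4))
        with pytest.raises(DataError, match=r"i_ac.*690.*3\b"):
            fit_slopes(frame)

    def test_too_few_distances(self):
        frame = _frame(np.array([2.0, 3.0]), np.ones(2), np.ones(2), np.zeros(2))
        frame.distances_cm = np.array([2.0, 3.0])
        with pytest.raises(ConfigurationError):
            fit_slopes(frame)

    def test_scale_invariance_of_slopes(self, quiet_physio, optics):
        """Global detector gain moves only the intercept, never the slope."""
        tr = simulate_physiology(quiet_physio, 600.0, ("baseline",), seed=3)
        raw, _ = synthesize_raw(tr, optics, seed=4)
        fit1 = fit_slopes(raw)
        raw.i_ac = raw.i_ac * 7.5
        fit2 = fit_slopes(raw)
        assert np.allclose(fit1.s_ac, fit2.s_ac, rtol=1e-12)
        assert np.allclose(fit2.c_ac - fit1.c_ac, np.log(7.5), rtol=1e-9)

    def test_phase_wrap_across_distances_is_repaired(self):
        r = np.array([2.0, 2.5, 3.0, 3.5])
        phase = 0.0 + r * 0.28
        wrapped = phase.copy()
        wrapped[2:] -= 2 * np.pi
        frame = _frame(r, np.ones(4), np.ones(4), wrapped)
        fit = fit_slopes(frame)
        assert fit.s_phi[0, 0] == pytest.approx(0.28, rel=1e-9)


class TestQcGate:
    def _fit_with_r2(self, r2_ac, r2_phi):
        shape = (1, 2)
        z = np.zeros(shape)
        return SlopeFitSeries(
            time_s=np.zeros(1),
            wavelengths_nm=np.array([690.0, 830.0]),
            s_ac=z, s_dc=z, s_phi=z, c_ac=z, c_dc=z, c_phi=z,
            r2_ac=np.asarray(r2_ac, dtype=float).reshape(shape),
            r2_dc=np.ones(shape),
            r2_phi=np.asarray(r2_phi, dtype=float).reshape(shape),
        )

    def test_rejects_low_amplitude_r2_at_one_wavelength(self):
        fit = self._fit_with_r2([0.94, 1.0], [1.0, 1.0])
        assert not qc_gate(fit)[0]

    def test_boundary_equality_passes(self):
        fit = self._fit_with_r2([0.95, 0.95], [0.95, 0.95])
        assert qc_gate(fit)[0]

    def test_perfect_fit_passes(self):
        fit = self._fit_with_r2([1.0, 1.0], [1.0, 1.0])
        assert qc_gate(fit)[0]

    def test_dc_r2_is_not_gated(self):
        fit = self._fit_with_r2([1.0, 1.0], [1.0, 1.0])
        fit.r2_dc[:] = 0.5
        assert qc_gate(fit)[0]


class TestFullChain:
    def test_noiseless_roundtrip_recovers_sto2(self, optics):
        """physiology -> raw -> fit -> invert -> unmix -> StO2, error <= 1e-6 %."""
        params = PhysioParams(
            venous_lag_s=0.0,
            events_per_condition={"baseline": 2},
            desat_magnitude_dist=DesatDistribution(kind="fixed", median_pct=5.0),
        ).without_noise()
        tr = simulate_physiology(params, 600.0, ("baseline",), seed=8)
        raw, _ = synthesize_raw(tr, optics, params, seed=9)
        tissue = process_raw(raw, optics)
        assert tissue["qc_pass"].all()
        err = np.max(np.abs(tissue["sto2"].to_numpy() - tr.sto2))
        assert err <= 1e-6

    def test_qc_monotone_in_perturbation_amplitude(self, optics):
        """Growing the single-distance contact artefact never raises any gated R^2."""
        s_ac, _, s_phi = (-1.9, None, 0.3)
        r = np.asarray(optics.distances_cm)
        prev = np.inf
        for scale in np.linspace(0.0, 3.0, 13):
            i_ac = np.exp(10.0 + r * s_ac) / r**2
            phase = 0.3 + r * s_phi
            i_ac[-1] *= np.exp(-scale)
            phase[-1] += 0.1 * scale
            frame = _frame(r, np.ones(r.size), i_ac, phase)
            fit = fit_slopes(frame)
            worst = min(fit.r2_ac[0, 0], fit.r2_phi[0, 0])
            assert worst <= prev + 1e-12
            prev = worst

    def test_rejection_count_matches_injected_segments(self, optics):
        params = PhysioParams(events_per_condition={"baseline": 1}).without_noise().with_(
            bad_contact_rate_per_hour=9.0
        )
        tr = simulate_physiology(params, 1200.0, ("baseline",), seed=5)
        raw, segs = synthesize_raw(tr, optics, params, seed=6)
        tissue = process_raw(raw, optics)
        from sleepnirs.simulate import bad_contact_sample_mask

        injected = bad_contact_sample_mask(tr.time_s, segs)
        assert tissue.attrs["n_qc_rejected"] == int(injected.sum())
        assert np.array_equal(~tissue["qc_pass"].to_numpy(), injected)
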