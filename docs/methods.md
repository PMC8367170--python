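# Methods

## The measurement model

### Photon diffusion in the frequency domain

A source intensity-modulated at frequency `f` (default 110 MHz,
`ω = 2πf`) launches photon-density waves into tissue, treated as a
homogeneous semi-infinite medium with absorption coefficient `µa`,
reduced scattering coefficient `µs′` (both 1/cm) and refractive index
`n = 1.4` (`v = c/n`). At source-detector distance `r`, the detected
mean intensity `I_DC`, modulation amplitude `I_AC` and phase delay `φ`
obey straight-line laws:

    ln(r²·I_AC) = r·S_AC + C_AC
    ln(r²·I_DC) = r·S_DC + C_DC
    φ           = r·S_φ  + C_φ

With `Q = sqrt(1 + (ω/(v·µa))²)` the slopes are, analytically,

    S_AC = −sqrt( (3µa(µa+µs′)/2)·(Q+1) )
    S_φ  = +sqrt( (3µa(µa+µs′)/2)·(Q−1) )
    S_DC = −sqrt( 3µa(µa+µs′) )            (the ω→0 limit of S_AC)

These closed forms are the exact inverses of the slope-pair inversion

    µa  = ω/(2v) · (S_φ/S_AC − S_AC/S_φ)
    µs′ = (S_AC² − S_φ²)/(3µa) − µa

which can be checked by substitution: `S_φ/S_AC − S_AC/S_φ =
2/sqrt(Q²−1) = 2vµa/ω` and `S_AC² − S_φ² = 3µa(µa+µs′)`. The test
suite verifies the round trip numerically to ≤1e−9 relative error over
a `µa ∈ [0.05, 0.3] × µs′ ∈ [5, 15]` grid (it is exact to machine
precision).

The inversion uses the (S_AC, S_φ) pair; S_DC is retained for
diagnostics only. Slope fitting is ordinary least squares per timepoint
per wavelength over the four distances (2, 2.5, 3, 3.5 cm); no temporal
windowing precedes the inversion — smoothing happens downstream on the
derived series. A constant regressand (zero residual, zero slope) is
reported with R² = 1, since the line fits perfectly; the textbook ratio
would be 0/0.

### Quality gate

A frame is discarded when the amplitude or phase regression has
R² < 0.95 at either wavelength — the signature of poor probe-skin
contact or light shunting along the skin. The rule is strictly
"smaller than": R² = 0.95 passes. The DC regression is reported but not
gated. Frames whose inversion yields `µa ≤ 0` or `µs′ ≤ 0` are excluded
the same way and counted separately; phases are defensively unwrapped
across distances (2π jumps are repaired and logged). The gate is
evaluated per sample; whether an instrument would gate per sample or
per epoch is an interpretation, made configurable through `r2_min` and
documented here.

### Chromophores and saturation

Absorption at wavelength λ is attributed to oxy- and deoxyhemoglobin:
`µa^λ = ε_HHb^λ·C_HHb + ε_HbO2^λ·C_HbO2` (natural-log convention, ε in
1/(µM·cm)). Two wavelengths give the closed-form unmixing; tissue
saturation is `StO2 = 100·C_HbO2/(C_HbO2 + C_HHb)`. The shipped
extinction coefficients are the Prahl/Gratzer compilation values at
690/830 nm (tabulated decadic 1/(cm·M), converted by ×ln10×1e−6);
they are configuration, not constants, since instruments differ in the
compilation they adopt.

## The synthetic recording generator

The generator emulates a split-night protocol: total duration divided
evenly across condition labels (a baseline hour, then one label per
CPAP pressure step). Within each segment, hypopneas are scheduled
non-overlapping with guard margins (45 s before, 50 s after) so every
event has a clean pre-event baseline window and nadir search region;
counts come from `event_rate_per_hour` (default 20/h, the scale of a
titration night) or are pinned exactly via `events_per_condition`.

Arterial saturation dips along a trapezoid (ramp 8 s, duration
uniform 30–60 s, both configurable) with magnitudes drawn from a
lognormal (median 4%, σ=0.45) truncated by rejection to [1, 15] % —
truncation, not clipping, so the 15% analysis cap is respected by
construction in default runs. The cap may be raised to exercise the
exclusion path.

The venous compartment follows the arterial deviation with gain
`κ ∈ [0, 1]` and a pure transport delay (`venous_lag_s`, default 10 s):
`SvO2(t) = SvO2_base − κ·ΔSaO2(t − lag)`. A first-order relaxation was
considered and rejected: it reaches the full κ·Δ depth only
asymptotically, which would make the per-event attenuation factor
depend on event duration and break the exact closed-form oracle
`arm_OD/finger_OD = a + b·κ` that anchors the tests. The venous
baseline is derived from the configured `baseline_StO2` (default 68.8%,
giving SvO2 ≈ 57% at the 0.30/0.70 AVR default); κ and the lag are
**placeholders chosen for plausibility, not literature claims** — no
invasive measurement of the venous response during sleep hypopnea
exists to calibrate them.

StO2 is the exact AVR mixture of the two (identity holds pointwise to
1e−12 with zero noise). The fingertip channel samples SaO2 on its own
1 Hz clock (a typical polysomnography oximeter rate; the arm channel
runs at the instrument's 5.2 Hz) plus 0.1% Gaussian sensor noise.

Raw frames follow by the forward slope model with per-wavelength
constant `µs′` (desaturation is modelled as an absorption change only;
scattering changes during events are second-order and not analyzed
downstream). Noise terms:

- hemodynamic oscillations as hemoglobin-concentration ripples —
  cardiac 1.1 Hz (0.3 µM, nearly pure HbO2), respiratory 0.25 Hz
  (0.5 µM) and slow/Mayer waves at 0.1 Hz (0.8 µM). The slow wave sits
  deliberately just above the 0.08 Hz cutoff so the filter genuinely
  removes it. At 5.2 Hz sampling the cardiac component is aliased;
  this mirrors the instrument and is filtered out, not corrected.
- multiplicative log-normal intensity noise (0.5%) and additive phase
  jitter (2 mrad) per sample/distance/wavelength.
- bad-contact segments (default ~1/h, 5 s) at the farthest distance:
  ln-amplitude offset −1.0 and phase offset +0.25 rad. These values
  were chosen by leverage analysis of the 4-point regression so that
  both gated R² fall convincingly below 0.95 (phase R² ≈ 0.8–0.94),
  while ordinary noise keeps R² ≈ 0.9998.

All randomness flows from one seed through named substreams
(physiology, then optics), so identical configurations reproduce
byte-identical reports.

## Signal conditioning

The StO2 series is low-pass filtered below 0.08 Hz with a linear-phase
FIR designed by the window method (Hann window). The default order
targets a ≈0.05 Hz transition band: `numtaps ≈ 3.1·fs/0.05` → 323 taps
at 5.2 Hz. Applied as a centered symmetric convolution with reflection
padding, the filter is exactly zero-phase; stop-band attenuation at
1 Hz is ≈139 dB (the contract tested is ≥40 dB). Quality-gated samples
are bridged by linear interpolation for the convolution — never
zero-filled — and remain masked afterwards.

Robust LOWESS (tricube weights, 2 bisquare iterations) smooths the
filtered series. At the operation level the span is the conventional
fraction-of-data (default 0.1, appropriate for the few-hundred-sample
windows the operation is typically applied to). At pipeline level a
fractional span would scale with recording length and flatten every
event, so the run configuration expresses the span as a fixed **15 s
time window**: below the shortest event duration (30 s), comparable to
the low-pass cutoff period (12.5 s), and empirically preserving event
nadirs to within ~1% while still suppressing spikes. Long runs use an
evaluation grid thinned to one regression per 2 s
(`lowess_delta_s`, linear interpolation in between; exact when 0).

## Event desaturation

For each annotated hypopnea (duration ≥ 10 s by definition; scoring
itself is upstream of this package):

    baseline = mean of the trace over the 30 s before event start
    nadir    = min of the trace from event start to 30 s past event end
    OD       = max(0, baseline − nadir)

The 30 s nadir search extension reflects the physiological lag between
airflow recovery and the saturation nadir; both windows are
configurable. The OD formula itself is a design decision — clinical
scoring guidelines describe the drop pictorially rather than
algebraically. Gap-masked samples are excluded from both windows; an
event is skipped (and logged) when its trace coverage is incomplete,
its baseline window is fully masked, or >25% of its search window is
masked (the nadir could be hiding in the gap).

Channels are paired strictly by event id. Events with finger_OD > 15%
are excluded from all statistics (strictly greater: 15.0% is retained)
but kept in the output ledger with a reason. Normalized arm OD is
`100·arm_OD/baseline_StO2` — the drop as a percentage of the pre-event
tissue-saturation level; other readings of "normalized to baseline"
exist, and only this formula's behavior is claimed.

## Agreement statistics

Differences are fixed as `finger_OD − arm_OD` (positive when the
finger desaturates more). Bland-Altman uses the sample SD (n−1) and
limits of agreement `mean ± 1.96·SD` (the conventional normal-quantile
multiplier, not a t quantile); the CI of the mean difference uses the
Student t quantile at n−1 df. The one-sample t test is two-sided
against zero. Detection uses the inclusive criterion `OD ≥ 3%`.
The Spearman sweep restricts to subgroups `finger_OD ≥ cutoff` for
cutoffs 2–8%, with average-rank tie handling; subgroups with n < 3 or
a constant coordinate are reported as undefined rather than failing.
No multiple-testing correction is applied across the sweep. Reports
cover the baseline condition, each CPAP pressure step, the pooled CPAP
group and the overall pool, each for raw and normalized arm OD.

## Problem sizes and what the tests show

The acceptance checks run on synthetic recordings sized so the whole
suite completes in a few minutes: a 1200 s noiseless recording for the
full-chain StO2 round trip (error ≤ 1e−6%), a 1600 s run with four
injected bad-contact segments for the quality gate, and two 80 000 s
runs of 500 events each for mixing-parameter recovery (ratio of mean
ODs 0.65 ± 0.02 noiseless, ± 0.05 with default noise). The worked
example in the README is a two-hour, 40-event night.

Passing these tests demonstrates that the chain is internally
consistent — the inversion undoes the forward model, the conditioning
preserves event depths, the statistics implement their definitions —
under the generator's assumptions. It does **not** demonstrate
fidelity to real tissue: the generator is homogeneous and single-layer
(no skin/adipose overburden), its AVR and venous dynamics are fixed
parameters rather than physiology, events never overlap, and motion
artefacts beyond the single-distance contact break are absent. Real
recordings also carry per-patient correlation that pooled event-level
statistics ignore; the report deliberately reproduces that pooled
analysis, so any clustering adjustment must happen upstream.

## Known limitations

- Semi-infinite homogeneous diffusion only; no two-layer or curved
  geometries, no instrument calibration solver.
- The venous gain/lag defaults are undocumented placeholders (see
  above); conclusions about absolute arm_OD sensitivity should sweep
  them.
- Cardiac energy is aliased at 5.2 Hz sampling and removed only
  because it lands above the 0.08 Hz passband after aliasing.
- The SpO2 channel is a saturation trace with additive noise, not a
  photoplethysmogram; pulse-oximeter artefacts (motion, low perfusion)
  are out of scope.
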