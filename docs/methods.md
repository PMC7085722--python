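# Methods

This note documents the models behind `eskin_lpm`, the defaults and why
they were chosen, what the synthetic sessions do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Device model

The E-Skin sensor is a resistive strain gauge whose relative resistance
change per unit strain (gauge factor, GF) is piecewise constant: 0.309
for strains in 10–30 % and 0.122 for 30–100 %. The forward map
`strain_to_resistance` is the continuous piecewise-linear curve implied
by those two regimes with the breakpoint fixed at ε = 0.30. The
characterisation estimator (`estimate_gauge_factor`) fits the slope of
(R−R₀)/R₀ against ε over a chosen strain range **with a free
intercept**: above the breakpoint the relative-resistance curve carries
the accumulated low-regime offset, so a through-origin fit would not
return the high-regime sensitivity. On noise-free forward-model data the
estimator returns the configured GF exactly in either regime.

The ADC operates at 3.3 V reference and 5 mA supply over 12 bits, so
counts and ohms are related linearly with 4096 ADU ↔ 660 Ω (one quantum
≈ 0.161 Ω). Quantisation is round-half-up followed by clamping to
[0, 4096]; clamping is part of the contract, not an error.

**Raw-count polarity.** The deployed device's raw ADU reading *falls*
when the sensor stretches even though its resistance rises (a
consequence of the sensing circuit, which this package does not model).
The simulator honours that behaviour: it presents the ADC with
`rest_resistance − ΔR(t)` (default rest reading 330 Ω, mid-scale), and
the preprocessing stage defines resistance change as
`baseline − Y(t)`, which is zero at rest and positive on stretch for
exactly this polarity. Downstream stages never see the sign convention.

**Unstrained resistance R₀.** R₀ is a free parameter. Device
characterisation defaults to R₀ = 100 Ω. Simulated *sessions* default to
R₀ = 1400 Ω: with GF 0.309 and a realistic peak skin strain of 0.30
during a 55° flexion, that gives a peak resistance change of ≈130 Ω —
the signal scale on which a ±6.9 Ω onset threshold sits at the same
relative depth (≈5 %) as a ±3° threshold does on a 55° movement, which
is the regime the detection analysis assumes. A much smaller R₀ would
push the resistance threshold deep into the ramp and make the onset
comparison between the two instruments meaningless.

**Durability.** `simulate_cyclic_test` cycles a triangular strain wave
(default 1000 cycles at 30 % strain, 0.4 Hz; the 10 % level used in some
bench tests is a parameter) through the forward model with a
multiplicative early-cycle perturbation decaying as
`0.02·exp(−cycle/150)`. The perturbation scales the resistance *change*,
so the released (zero-strain) resistance always returns exactly to R₀;
peak variation over the final 10 % of cycles is below 1 % ("settled").

## Synthetic sessions

A session emulates one participant performing each configured movement
for 5 repetitions per set over 3 sets (15 repetitions per movement).
Angle trajectories are raised-cosine ramps — rest at 0°, ramp to the
peak, hold, ramp back — chosen because only the endpoints and hold
durations of the real movements are known and the raised cosine is
smooth, differentiable and overshoot-free. Defaults:

| movement | peak (°) | ramp (s) | hold (s) |
|---|---|---|---|
| flexion | +55 | 3 | 10 |
| extension | per-rep uniform in [−17, −10] | 3 | 3 |
| anterior / posterior pelvic tilt | ±15 | 3 | 3 |
| left / right lateral flexion | ±25 | 3 | 3 |
| left / right rotation | ±30 | 3 | 3 |

Flexion and extension peaks and the flexion hold follow the measured
protocol; pelvic tilt, lateral flexion and rotation peaks are not
reported anywhere and use typical adult lumbar ranges. Signs follow the
convention flexion/anterior/left = positive.

Rests between repetitions are 6 s plus a per-repetition uniform draw in
[0, 0.5] s. The jitter matters: participants cannot reproduce their
timing exactly, and perfectly periodic repetition blocks would alias
against the 1-s analysis bins, pinning every threshold crossing at the
same within-bin phase — a degenerate condition real data never shows.

**Coupling.** Skin strain per channel is `coef·|θ|^exponent` (sustained
channels) or `coef·|dθ/dt|` (transient channels), clamped to
[0, max_strain]. The default coupling encodes the placement findings the
classifier relies on:

* flexion loads the bottom vertical sensor about twice as strongly as
  the top (peak strains 0.30 vs 0.15);
* extension is *nonlinear* on the bottom sensor (exponent 1.4) and
  transient on the top sensor, producing the characteristic two spikes —
  one per ramp — at the start and end of each repetition;
* pelvic tilt is sustained on the top sensor and transient (double
  spike) on the bottom for posterior tilt, while the bottom sensor barely
  responds to anterior tilt;
* lateral flexion loads the contralateral diagonal sensor ~1.8× more
  than the ipsilateral one;
* rotation loads the diagonals near-equally (ratio ≈ 1.08) but the
  ipsilateral channel responds 1.5 s later, so the contralateral sensor
  rises first.

**Timing, noise, drift.** The strain trajectory leads the angle
trajectory by `onset_lead_s` (default 1.0 s — the skin pre-stretch);
whether the lead is constant across movements is unknown, so it is one
configurable constant. E-Skin channels sample at 15 Hz; the angle
channel at a rate drawn uniformly in 19.0–19.8 Hz per session. Gaussian
noise (default sd 2 ADU) is added before quantisation; the angle channel
carries 0.3° noise. After each completed repetition the E-Skin rest
level drifts up by `drift_per_rep` (default 0.25 Ω), emulating adhesive
slip; the default keeps the accumulated offset over 15 repetitions below
the 6.9 Ω onset threshold. All randomness flows from one integer seed;
identical configuration and seed give bit-identical sessions.

**What the simulator does not emulate.** 3-D trunk kinematics, soft
tissue artefacts, EMG, clothing interference, inter-individual skin
variability, temperature effects and hysteresis beyond the decaying
cyclic transient. Passing tests therefore demonstrate that the analysis
stages are correct and internally consistent with the encoded response
patterns — not that the classifier or calibration would achieve these
numbers on human data.

## Preprocessing

The scalar Kalman smoother iterates k = p/(p+r);
estimate ← last + k·(measurement − last); p ← (1−k)·p + |last−current|·q,
with r = 4, p = 4, q = 0.05. The recurrence leaves the initial state
unspecified; the first estimate is initialised to the first measurement,
making a constant input an exact fixed point. Smoothing is applied to
raw counts before unit conversion (as on the acquisition device) and can
be moved after conversion or disabled. The reference angle channel is
not smoothed by default (whether the clinical instrument's output was
smoothed is unknown; both options are exposed).

The baseline is the mean over the first 5 s of the recording (static
standing); the window offset is configurable. A series "covers" the
window if it spans it to within one nominal sample period, so 75 samples
at 15 Hz cover [0, 5) s. Second bins are half-open [s, s+1) on
floor(timestamp_ms/1000); empty bins are never fabricated, and alignment
is a strict inner join that drops (and counts) bins missing from any
channel.

The ±6.9 threshold on resistance change is interpreted in ohms, the unit
Eq.-(5)-style conversion yields; the source analysis never states the
unit explicitly.

## Calibration

Single-predictor fits use the closed-form least-squares slope/intercept;
statistics are R², adjusted R² = 1 − (1−R²)(n−1)/(n−k−1), and a
two-tailed p-value — a slope t-test (n−2 df) for one predictor, the
overall F-test for the two-predictor variant (fits are computed via
statsmodels OLS; the test suite checks them against explicit
normal-equation solves). Per-second samples are treated as independent
when computing p, replicating the original analysis convention even
though consecutive seconds are autocorrelated — the p-values are
optimistic and should be read accordingly.

The train/test split is chronological: the first 10 repetitions of a
movement train the model, the last 5 are held out, and MAE in degrees is
reported on the held-out seconds. Chronological splitting is
reproducible and respects drift (train precedes test in time). Rest
seconds inside repetition windows are included in fitting by default
(the recordings being modelled are continuous), with a flag to exclude
them. A zero-variance predictor raises a degenerate-fit error; a
rank-deficient two-predictor design raises a collinearity error — on
idealised noiseless sessions the two vertical channels are exactly
proportional, so the pipeline records the "both" variant as degenerate
rather than fitting it.

## Detection

`detect_onsets` opens an event at the first sample whose deviation from
the rest level exceeds the threshold after a sub-threshold stretch; an
ongoing excursion never re-opens an event, and crossings within the
refractory period (default 3 s, matching the few-second rests) are
suppressed. The pipeline's detection stage locates onsets inside each
repetition window and re-estimates the rest level from the rest seconds
preceding each repetition (drift compensation); without it, accumulated
drift over a long multi-movement session would hold channels permanently
outside a fixed band.

The response-time difference is the mean over paired repetitions of
(angle onset − E-Skin onset), positive when the skin channel leads.
At the default conditions the recovered value is ≈0.7–0.9 s for a
configured 1.0 s lead: the Kalman smoother delays the E-Skin threshold
crossing by roughly a quarter second while the angle channel is not
smoothed, and the 1-s analysis bins quantise each paired difference.
The recovery is within one analysis bin, which is the resolution the
per-second protocol supports.

Classification is deliberately rule-based (no trained model). Free
parameters: the dominance ratio separating "asymmetric" from
"near-equal" channel pairs (1.3), and the spike criterion (≥2 peaks at
≥50 % of the channel maximum with ≥40 % prominence). The anterior- vs
posterior-tilt distinction rests on whether the bottom channel shows its
double-spike signature — an encoding of the generator's patterns, since
the underlying protocol reports that the bottom placement cannot fully
capture anterior tilt. Conflicting evidence lowers a confidence flag
("low") instead of raising.

## Problem sizes

Unit and property tests run on sessions of 2–15 repetitions of single
movements (a 15-repetition flexion session is ≈340 s of signal at
15–20 Hz); the full default pipeline — eight movement variants × 15
repetitions, ≈2000 s of signal across five channels — runs in under a
second. Monte-Carlo checks use 100 random instances (regression oracle,
parameter recovery) or 10–20 seeds (lead recovery).

## Known limitations

* The calibration MAEs and R² values produced on synthetic sessions
  depend on the chosen coupling and noise defaults; they characterise
  the pipeline, not any sensor's clinical accuracy.
* The classifier's rules are tuned to the encoded placement patterns;
  on real data the thresholds and spike criteria would need
  re-estimation.
* p-values inherit the independent-samples convention noted above.
* The circuit relating resistance to falling raw counts is not
  modelled; only its observable polarity is.
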