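# Methods

`myocoupling` quantifies load-sharing between forearm muscles during
cyclic isokinetic endurance contractions from multichannel surface EMG.
This note documents the models and procedures, the parameters that
matter, the synthetic cohort the package validates itself against, and
the numerical choices and limitations a user should know about.

## Signal chain

Raw input per muscle is a linear-array recording: 7 single-differential
(SD) channels at 2048 Hz, 5 mm inter-electrode distance, plus dynamometer
torque/angle/velocity at 100 Hz synchronised by a trigger.

1. **Band-pass 20–350 Hz**, 4th-order Butterworth, applied
   forward–backward (zero phase, effective order 8). Envelope timing
   across muscles is what the coupling analysis measures, so phase
   distortion is not acceptable.
2. **Double differential (DD)**: DD_i = SD_{i+1} − SD_i, attenuating
   crosstalk — the dominant confound in forearm recordings.
3. **Channel selection.** For each adjacent DD pair the normalised
   cross-correlation peak gives the correlation coefficient CC and, via
   its sub-sample delay (parabolic interpolation around the peak), the
   motor-unit conduction velocity CV = d/Δt. At 2048 Hz and 5 mm,
   physiological delays are only 1.5–3.4 samples, so integer-sample
   delays would quantise CV far too coarsely for the gate. A channel
   qualifies if CC > 0.7, 3 < CV < 7 m/s, and it passes an automatic
   artifact screen; among qualifiers the highest CC wins. The screen
   replaces visual inspection with two reproducible criteria: amplitude
   outliers |z| > 14 on the filtered trace (clipping, spike bursts;
   threshold chosen from the measured separation between clean synthetic
   channels, max |z| ≲ 11, and contaminated ones, ≥ 18) and > 20 % of
   spectral power below 20 Hz on the *unfiltered* trace (baseline wander
   is removed by the zero-phase band-pass, so it must be screened before
   filtering).
4. **Envelope**: full-wave rectification, centered 400 ms moving average
   (edges truncated), polyphase anti-aliased resampling to 20 Hz on the
   exact rational ratio 5/512, then z-normalisation (mean and SD stored).
   The non-negative pre-normalisation envelope is retained for the
   co-activation index, whose min() semantics require non-negative
   signals.
5. **Cycle segmentation**: rising zero-crossings of the torque signal
   smoothed with a 100 ms moving average delimit extension→flexion
   cycles; crossings closer than 0.3 s are removed in pairs (alternation
   preserved) since genuine half-cycles at 60–180 °/s over 70° last far
   longer. Recordings typically start at the beginning of an extension
   and end at the close of the last flexion, so a leading/terminal
   boundary is restored when a plausible span (0.5–1.6 × the median
   cycle) is left over; on noise-free synthetic torque the recovered
   cycle count is exact.

Kinematic summaries per cycle: plateau velocities (mean of samples beyond
half the directional peak), range of motion, duration, and the
session-level Torque_final/initial ratio — the mechanical signature of
fatigue.

## Delay embedding and cross-prediction

Each envelope segment is lifted to a state trajectory: row t of the
embedding is [s_t, s_{t+DT}, s_{t+2DT}, s_{t+3DT}] (embedding dimension
ED = 4), giving P = NS − 3·DT rows. DT is a quarter of the subject's mean
cycle (≈ 10 samples at 20 Hz for 2 s cycles), so one row spans a full
cycle of activity.

To predict muscle B from muscle A at horizon PH: for every admissible row
t of A's embedding, the k = 3·ED = 12 nearest rows (Euclidean distance,
leave-one-out, ties broken by lower index; rows whose image t+PH falls
beyond the last usable index are excluded) define a local affine model
fitted by least squares from neighbour states to B's envelope at
(neighbour + PH); the model is evaluated at row t. Goodness over all t is
R² = 1 − SSE/SST, clamped to [0, 1]; stitched across PH = 1…200 samples
(50 ms resolution, 10 s) it gives the prediction-horizon profile, and

* the **long-term area** (sum of R² over the 200-point grid, range
  0–200) indexes coupling for the whole-test and three-stage analyses;
* the **short-term area** (PH ≤ 0.5 s, 10 points) drives the sliding
  analysis.

### Numerical form of the local fit

The affine fit is computed in centered form: the intercept is carried by
the neighbourhood means, and the linear part is solved on the centered
neighbour matrix by a truncated SVD (via the eigendecomposition of the
5×5 normal matrix in the batched engine). Singular values below
max(10⁻⁸·s_max, 0.1·σ·√k) are truncated, where σ is the global standard
deviation of the embedded signal: a neighbourhood direction with less
spread than a tenth of the signal scale carries measurement noise rather
than state information, and fitting along it amplifies target noise
(for a nearly noiseless periodic envelope every neighbour shares a phase
and the untruncated fit inflates prediction error severalfold). Truncated
fits degrade smoothly toward the neighbour-target mean — the zeroth-order
fallback of locally linear forecasting — which is exact when all
neighbour rows coincide. The rule is scale-equivariant, so the analysis
is invariant under common positive rescaling of the envelopes. The
vectorised engine, the per-point API and the test-suite reference
implementation all apply the identical rule.

By default the scalar future envelope sample is predicted; a config
switch (`target_mode="vector"`) instead predicts the target's embedded
vector with R² averaged across coordinates. Neighbour search excludes
only the query row; a Theiler window is available (default 0) for
sensitivity analyses. With no Theiler exclusion, smooth envelopes carry
some predictability through temporal autocorrelation alone — the null
behaviour checks therefore use white-noise envelopes, and coupling
comparisons are always made against matched decoupled controls.

## The three analysis schemes

1. **Whole test**: one curve and 10 s area over the entire session.
2. **Staged**: the same index on three 15-cycle segments — initial
   (cycles 1–15), final (last 15), middle centered at
   floor((TNC−15)/2)+1; stages overlap exactly when the subject completed
   fewer than 45 cycles. Between-stage contrasts are paired Wilcoxon
   tests within group.
3. **Sliding**: A's first 15 cycles are embedded once; a 15-cycle window
   of B advances one cycle at a time. Window samples are taken at the
   same *fractional* within-cycle phase of the shifted cycle, so cycle
   jitter does not misalign template and window, and horizons (PH ≤
   0.5 s) stay within the window. Because the fitted prediction is linear
   in the target values, per-query weights are precomputed and each
   window costs only a weighted gather. The course of short-term areas is
   normalised by its value at 0 %TNC (exactly 1 there) and summarised by
   the cumulative area under the normalised course on the %TNC axis at
   every 10 %TNC checkpoint — integrating on the %TNC axis makes
   checkpoints comparable across subjects with different cycle counts.

## Co-activation index

The reference measure: per cycle, nEMG is the non-negative envelope
divided by its own within-cycle SD; CI = 2·Σ min(nEMG_a, nEMG_b) /
(Σ nEMG_a + Σ nEMG_b) × 100 (rectangular sums; the time step cancels).
CI is symmetric, bounded in [0, 100], invariant to common and per-cycle
rescaling. Whole-test CI is the mean of per-cycle values (the integral in
its definition is written per duty cycle); staged and sliding schemes
mirror the cross-prediction schemes, including initial-value
normalisation of the 15-cycle moving-window course.

## Statistics

Rank-based tests throughout, two-sided, α = 0.05: Lilliefors-corrected
Kolmogorov–Smirnov for normality screening (estimated moments make the
naive KS anti-conservative), Mann–Whitney U between groups, Wilcoxon
signed-rank for paired within-group contrasts. Exact distributions are
used when both samples are ≤ 25 without ties, otherwise the
tie-corrected normal approximation with continuity correction. No
multiple-testing correction by default (per-comparison α, matching the
study design the package reproduces); Holm adjustment is available as an
option. Small-n p-values are verified against brute-force enumeration
over group assignments and sign patterns in the test suite.

## Synthetic cohorts

Human recordings for this protocol are not publicly available, so the
package ships a generator whose outputs carry known ground truth for
every stage.

**Kinematics.** Each ~2 s cycle is extension at +60 °/s (70° range),
pause, flexion at −180 °/s, pause; duration jitter (2 % SD) lives in the
pauses so the isokinetic plateaus stay at the device velocities. Torque
is a positive hump over the extension half and a smaller negative hump
over the flexion half, its amplitude decaying linearly to 30 % of the
initial value — the torque-decline regime of a fatiguing endurance test.

**Drives and coupling.** Muscle m's activation drive is
shape_m(phase) × exp(σ·mix_m − σ²/2) with

mix_m(t) = √α_m(c)·U(phase − lag_m) + √(1 − α_m(c))·v_m(t).

shape_m is a per-muscle bell over the cycle phase (extensors peak during
extension, FCR during flexion) on a baseline of 0.35 — the 400 ms-smoothed
envelope of this task never rests at zero. U is a smooth random function
of cycle phase shared by all muscles: the fine structure of the common
motor program, reproduced every cycle while coordination holds, modelled
as 90 % canonical (task-determined, common to all subjects) plus 10 %
subject-specific. v_m is private AR(1) noise (0.7 s time constant). The
shared-variance fraction α_m(c) = coupling0_m·e^(−decay·c) at cycle c is
the ground-truth coupling; mixing in square roots makes α exactly the
shared fraction. The lags (0–150 ms across muscles) matter: a lagged
shared pattern gives the delay-embedded predictor genuine dynamical
structure to exploit while remaining largely invisible to the
instantaneous overlap that CI measures — the sensitivity contrast between
the two indices is thus a property of the generated physiology, not of
tuning.

**Array EMG.** A composite motor-unit action-potential train fires as an
inhomogeneous Poisson process (600 pulses/s at full drive — an
interference pattern, not separable units) convolved with a biphasic
~10 ms wavelet; successive SD channels are band-limited fractional delays
of the same train at d/CV (programmed CV 3.5–6.5 m/s), plus white noise
at 15 dB SNR. Optional artifact channels receive large 3–8 Hz wander and
spike bursts, which the automatic screen must reject.

**Cohort design.** Ten control-like subjects (coupling0 0.97 for all
muscles, decay 0.0165/cycle) vs ten patient-like subjects (decay
0.033/cycle — exactly twice — and an ECR deficit, coupling0 0.93), 60–75
cycles per subject. These conditions were chosen so that the generated
study reproduces the qualitative two-group structure the analysis is
meant to detect — a faster coupling decline in patients, detectable from
the cumulative normalised course at 50 %TNC with n = 10 per group in
over 80 % of cohort draws, while the co-activation course shows no group
difference in the large majority — with working margin, validated on
seed ranges disjoint from those used by the test suite (91 % and 95 %
respectively, 56 replicates).

**Decay-rate recovery.** The R² of the sliding scheme responds nearly
proportionally to the shared-variance fraction only near full coupling:
the leave-one-out estimator inflates the error term by roughly (1 + 1/k)
plus a phase-smoothing bias, and the clamp at zero flattens the low end.
`fit_decay_rate` therefore fits the log-linear slope only over windows
with normalised area ≥ 0.7, and `decay_probe_config` defines the
conditions under which the decay rate is identifiable: full initial
coupling, a clean (non-decaying) predictor muscle, no deterministic
shape, no cycle jitter, modulation in the linear range, decay programmed
on the target muscles. Under these conditions the median recovered rate
over 20 subjects is within ~15 % of the programmed value.

## What the synthetic validation does and does not show

Passing tests demonstrate that the pipeline recovers programmed
conduction velocities, cycle structure, torque decline, coupling levels
and coupling decay rates, that its two indices dissociate exactly where
they should, and that every computation is deterministic given seeds.
The generator does not model volume conduction, motor-unit recruitment
and rotation, innervation-zone geometry, electrode lift-off, or
fatigue-driven spectral compression of the action potentials; conclusions
about real recordings therefore rest on the method, not on these tests.
Whole-test areas of envelope-level synthetic subjects are lower than
typical published values for real forearm recordings, whose
400 ms-smoothed envelopes carry more short-horizon autocorrelation;
raw-level synthetic subjects, which pass through the full demodulation
chain, land in a comparable range.

## Performance and problem sizes

The analysis path is deterministic and vectorised: one 60–75-cycle
subject (raw EMG → envelopes → all three schemes over six + three muscle
pairs + CI) takes ~20 s on one CPU; a 20-subject cohort including report
generation runs in well under 15 minutes. Validation studies in the test
suite use envelope-level cohorts (the raw electrode layer is exercised
separately), 50 cohort replicates for the two-group contrast, and
20-seed batches for recovery checks.

## Known limitations

* CC for channel selection is computed over the full recording; the
  selection span for non-stationary hour-scale signals is unspecified in
  the underlying protocol.
* The initial-value normalisation of sliding courses divides by a single
  window's estimate; subjects whose initial window sits near the R²
  clamp produce unstable normalised courses (reported as errors, and
  summarised per subject by the median across the three ECR pairs).
* Whether the original formulation predicts the scalar future sample or
  the embedded vector is ambiguous; both are implemented, scalar default.
* The Lilliefors p-value (statsmodels table method) is range-limited at
  the extremes.
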