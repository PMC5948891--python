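# Methods

## The task and the pipeline

A session alternates two cued mental states — relaxation and pedaling motor
imagery — while 30 EEG channels (10-10 montage) are recorded at 500 Hz.
Detection rests on event-related desynchronization (ERD): imagery suppresses
the mu rhythm (8–12 Hz, and more weakly the beta band) over the leg area of
the motor cortex, which sits at the vertex (Cz). The online pipeline is,
per 1 s epoch advanced by 200 ms:

1. epoch extraction, skipping the first 2 s of each 5.8 s task
   (cue-reaction transient), 15 epochs per task;
2. DC removal, 50 Hz notch, 45 Hz low-pass;
3. surface-Laplacian re-reference over the full montage, then reduction to
   the nine motor-area electrodes;
4. Burg AR(16) power spectrum evaluated at the integers 6–30 Hz, normalized
   to relative power per (epoch, electrode);
5. one feature per electrode: the relative power at that electrode's
   *optimal frequency*, selected on the training trials as the frequency
   with the largest |mean relax − mean imagery| normalized power;
6. standardization and a binary RBF-SVM, trained on trials 1–4 of the same
   session; trials 5–10 are classified online, one prediction per 200 ms.

Real-time accuracy is the percentage of correct predictions among all
predictions of the evaluation trials; chance level is 50 % on the balanced
protocol. The feedback bar of a task grows by one per correct prediction.

## Synthetic sessions

The generator's job is to produce sessions where the quantity every stage
estimates is known exactly.

**Source model.** The mu rhythm is a sinusoid at `mu_center_hz` with random
phase, slow (~1 s correlation) amplitude jitter of 5 % and a slight
(±0.2 Hz) frequency wander; an optional beta component is generated the same
way. During imagery the source amplitude is multiplied by
`sqrt(1 − ρ·day_curve[day])` with 100 ms cosine ramps at task boundaries
(no broadband clicks), so band *power* drops by exactly `ρ·day_curve[day]`
and the ground-truth ERD is `−100·ρ·day_curve[day]`, linear in ρ.

**Spatial model.** The source projects to the scalp with a Gaussian weight
over the 2D-projected 10-10 positions, centered at Cz with a scale of ~1.6
electrode spacings, so Cz and its ring (C1/C2/FC1/FC2/CP1/CP2, then C3/C4)
carry most of the rhythm — the reason those nine electrodes are the
discriminative set. There is no volume-conduction head model.

**Noise.** Per-channel independent 1/f-power noise (RMS `noise_amplitude`),
plus one common-mode 1/f component at half that RMS shared by all channels
(this is what the Laplacian's common-mode rejection is exercised against),
plus a 50 Hz line component with per-channel gains in [0.8, 1.2].

**Cohorts.** Subjects draw mu center, amplitudes, ρ ∈ [0.3, 0.45] and noise
levels from fixed ranges. Two presets differ only in `day_curve`: the
stimulation preset applies the subject's full suppression from day 1
(multipliers all 1), the sham preset ramps from 0.35 to 1.0 across the five
days, emulating unassisted learning of the imagery task. The ramp endpoints
are illustrative — chosen to reproduce the qualitative pattern
(sham near chance on day 1, converging to the stimulated group later) —
not calibrated against any quantitative learning curve.

**What passing tests do not show.** Real EEG has broadband non-stationarity,
eye/muscle artifacts, electrode drift, inter-channel noise correlation and
imperfect cue compliance; none are modeled (artifact injectors are out of
scope). Accuracies on these sessions therefore bound what the pipeline can
do under its own assumptions, not human performance.

## Parameters that matter

| parameter | default | meaning / why |
| --- | --- | --- |
| task / cross duration | 5.8 s / 3.0 s | protocol timing; a cross precedes every task, including a trial's first |
| epoch length / shift | 1.0 s / 0.2 s | 15 epochs per task after the 2 s discard |
| training trials | 4 of 10 | fixed split, no cross-validation; mirrors the online design |
| AR order | 16 | ~fs/30 for 500-sample epochs; resolves the 1 Hz feature grid (configurable) |
| notch quality Q | 10 | ring-down ~0.1 s fits a 1 s epoch; Q=30 leaves 0.13 RMS of a unit 50 Hz tone inside the window |
| SVM C / γ | 1 / median heuristic | γ = 1/median pairwise squared distance of standardized training features; deterministic |
| mu amplitude / noise RMS | 5 µV / 3 µV | realistic scalp mu SNR; at these levels single-session accuracy lands in the 55–75 % range |
| ρ (suppression fraction) | 0.3 | moderate ERD depth (−30 %), the regime the analyses probe |

## Numerical choices

- **Per-epoch high-pass = demeaning.** The nominal DC-removal filter
  (4th-order Butterworth, 0.05 Hz) has a zero-phase transient that decays
  over tens of seconds; applied forward-backward inside a 1 s window, any
  edge discontinuity smears across the whole epoch (measured: 0.36 RMS of
  artifact on unit tones). On a 1 s window that filter's only intended
  effect is removing DC, so the epoch path subtracts the epoch mean
  exactly; the causal streaming mode (`filter_recording_causal`) runs the
  true Butterworth with state carried across the session.
- **Notch and low-pass** are zero-phase (forward-backward) with maximal
  reflection padding, chunked over epochs to bound peak memory.
- **Laplacian**: all 29 other electrodes, weights ∝ 1/distance normalized
  to sum 1 per target, over azimuthal-equidistant projections of the
  standard idealized 10-10 positions (from MNE); applied before electrode
  selection. Duplicate coordinates are rejected (zero distance).
- **Burg recursion** is implemented vectorized over (epoch × channel)
  batches — a session needs ~27 000 fits — and agrees with the independent
  statsmodels implementation to machine precision; periodograms are the
  spectral-peak oracle. Signals are demeaned before fitting; an all-zero
  epoch raises rather than returning a fake spectrum.
- **"Power at a frequency"** means the AR density evaluated at the integer
  frequency (matching the 1 Hz-resolution reading), not band-integrated.
  Normalization is per-epoch, per-electrode relative power over the 25-bin
  grid; optimal-frequency ties break toward the lowest frequency.
- **ERD uses periodogram bins, not Burg point powers.** ERD is a
  ratio-of-mean-powers statistic. The height of an estimated AR peak for a
  high-SNR narrowband rhythm is heavy-tailed (the fitted pole approaches
  the unit circle), and session-level means of Burg point powers scatter
  wildly (observed −50 % to +90 % for a true −30 %). The 1 s periodogram's
  1 Hz bins integrate the band, are linear in band power, and recover
  −100·ρ within ±3 points; `compute_power_table(..., method=...)` exposes
  both estimators, and classification keeps the Burg path (its
  normalization and argmax don't depend on absolute peak height).
- **Feature standardization** before the RBF kernel is deliberate: relative
  powers differ by orders of magnitude across electrodes and frequencies.
  Models store support vectors, dual coefficients and scaler parameters as
  plain arrays (JSON-serializable, library-independent prediction).
- **Time bookkeeping** is in real seconds; sample indices round t·fs
  (0.2 s · 500 Hz is an exact 100-sample shift); window counting uses a
  1 ns tolerance so the last exactly-fitting epoch (start 4.8 s) is kept.
- **Schedules** are rejection-sampled balanced permutations (uniform over
  admissible orders); per-trial seeds spawn from the session seed.

## Problem sizes used by the test and acceptance runs

Structural tests run on reduced protocols (2–5 tasks per type, 2–3 trials);
ground-truth band-power ratios use a full noise-free session (100 tasks per
class, sampling std ≈ 0.01, matching the ±0.02 assertions). ERD recovery
and mu-band concentration use one full low-noise session (ρ = 0.3); the
accuracy-vs-ρ sweep runs one full session per ρ ∈ {0, 0.15, 0.3, 0.5}; the
63-optimal-frequency count runs 7 subjects on training-trials-only sessions
(feature selection uses only trials 1–4, so this changes nothing but cost).

## Known limitations

- No EDF+ *writer* (sessions export to the TSV.gz + JSON container; EDF+ is
  read via MNE).
- ERD ground-truth linearity holds at the source; measured ERD shrinks
  toward 0 as background noise grows (a property the tests assert, and a
  caution for interpreting absolute ERD from noisy channels).
- The sham/stimulation contrast is a generator preset, not a physiological
  model of stimulation; only its qualitative day-1 ordering is meaningful.
- Inferential statistics (sphericity tests, mixed ANOVA, corrected pairwise
  comparisons) are out of scope; the cohort tables are tidy inputs for any
  external statistics package.
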