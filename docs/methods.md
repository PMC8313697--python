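# Methods

This note documents the models, detection rules and numerical choices
behind `stopcsp`, and what the synthetic-data generator does and does not
emulate.

## The scientific question

The package operationalises a single question: does the duration of the
TMS-evoked cortical silent period (CSP) — a temporal index of
GABA_B-mediated intracortical inhibition in primary motor cortex — track
individual differences in behavioral action stopping, indexed by the stop
signal reaction time (SSRT)?  Both measures are noisy, participant-level
scalars, so the analysis chain is: per-trial extraction → per-participant
aggregation → screening → robust correlation and cross-validated
prediction across participants.

## Behavioral model and simulator

The stop-signal task simulator implements the independent horse-race
model.  On every trial a go process finishes at an ex-Gaussian time
`T_go ~ Normal(go_mu, go_sigma) + Exp(go_tau)`; on stop trials a stop
process starts at the stop signal delay (SSD) and finishes after a
Gaussian latency truncated at zero, `S ~ N+(stop_mu, stop_sigma)`.  A
response is emitted on a stop trial iff the go process wins
(`T_go < SSD + S`), the go finish beats the 1000 ms deadline, and the go
process did not fail outright (omission).  Omissions apply identically on
go and stop trials: an omitted go process cannot produce a response on
any trial type.  Trigger failures (the stop process never starting) are
supported but default to zero.

Defaults (units ms unless noted):

| parameter | default | rationale |
|---|---|---|
| go_mu, go_sigma, go_tau | 456, 54, 90 | ex-Gaussian mean 546, SD ≈ 105 — the observed scale of mean go RT |
| stop_mu, stop_sigma | 215, 20 | mean stop latency at the observed SSRT scale; trial-level SD is a standard-practice choice (no published value) |
| p_omission, p_choice_error | 0.02, 0.004 | reproduce ~2% go omissions and ~99.6% go accuracy |
| session | 32-trial practice (8 stop) + 5 × 96 trials (24 stop) | the task design; stop trials are exactly 25% |
| SSD staircase | start 250, step 50, bounds [0, 900] | 1-up 1-down tracking; bounds keep the stop signal displayable within the 1 s trial window |

The staircase raises the SSD after every successful stop and lowers it
after every failed stop, which drives p(respond|signal) to 0.5; across
100 simulated sessions the mean sits within ±0.02 of 0.5.  Practice
trials are generated and flagged but excluded from every statistic.

At the population level each participant draws a true CSP and a true mean
stop latency from a bivariate model sharing a latent standard-normal
trait z with loading λ = √|ρ|, so their correlation is exactly the
configured `coupling_rho` in expectation (default 0.6).  Participants
also draw a go-process location (`go_mu_sd` = 100 ms between subjects),
which reproduces the observed between-subject spread of mean go RT
(~105 ms) and, through staircase tracking, of mean SSD (~117 ms).
Resting motor threshold (48–61% MSO), MEP amplitude (0.49 ± 0.29 mV) and
MEP duration (35 ± 2 ms) are drawn per participant; rMT is metadata only.

Not emulated: sequential/fatigue effects (trials are i.i.d.), feedback
effects of the practice block, strategic slowing, and any drift of the
contraction level across the TMS session.  Passing tests therefore show
that the estimators recover the generating model's parameters, not that
they are robust to violations of race-model independence.

## SSRT: integration method

The integration estimator assumes the stop process finishes at the
p(respond|signal) quantile of the go RT distribution:

    SSRT = Q_go(p(respond|signal)) − mean SSD.

The go RT set includes choice-error responses, and every go omission is
replaced by the maximum observed go RT (a conservative, order-preserving
replacement: it can only push the quantile up).  The quantile is the nth
smallest value with n = round(p·N_go), rounded half away from zero and
clamped to [1, N_go] — the exact rounding convention inside the consensus
analysis code is not published; the sensitivity of this choice is O(1/N).
Mean SSD averages over all stop trials, successful or not, consistent
with the staircase logic.  Whether "RT on go trials" should include
choice errors is not published either; the default here includes them
(both choices differ by < 1 ms at the default error rate).

Screening applies five strict-inequality criteria: p(respond|signal)
outside (0.40, 0.60); go omissions > 25%; choice errors > 10%; mean RT on
failed stop trials above mean go RT (race-model violation); SSRT < 50 ms
(subsumes negative estimates).  Excluded participants are dropped, not
replaced — replacement is a recruitment act, not an analysis act.

## EMG synthesis

Each sweep is 600 ms at 8 kHz with the stimulus at 200 ms.  Tonic EMG is
band-limited (20–250 Hz Butterworth, filtered with generous padding and
cropped so the sweep is stationary) Gaussian noise scaled to an RMS of
0.05 mV, i.e. 30% of an MVC reference RMS of 0.167 mV.  The MEP is a
deterministic biphasic waveform — two half-sine lobes raised to the power
0.5 (45%/55% split, the second negative), normalised to the exact
peak-to-peak amplitude — inserted 22 ms after the stimulus with 35 ms
support.  The fractional exponent gives the fast edges and brisk central
zero crossing of real compound potentials; a smoothly windowed sine
instead spends several milliseconds near zero mid-MEP, which no
threshold-based offset rule survives.  From MEP onset until
`csp_duration` after MEP offset the tonic gain drops to `silence_floor`
(0.02) — the compound potential interrupts voluntary drive rather than
summing with it — followed by a 10 ms linear recovery ramp.  Per-pulse
CSP durations jitter with SD 8 ms around the participant's true value
(within-subject variability is not published).

Not emulated: 50 Hz interference, movement artifacts, electrode issues,
amplitude drift, or the multi-component shape of real MEPs; the stimulus
artifact is represented only by the detector's 5 ms blanking window.

## CSP and MEP detection

All landmarks are detected on the envelope — full-wave rectification
followed by a centred 5 ms moving average — with thresholds relative to
the pre-stimulus baseline window [−110, −10] ms: envelope mean m and SD s
there, plus the raw RMS for the contraction check.  Raw rectified EMG at
this SNR crosses any baseline-derived threshold continually, so the
envelope, not the raw signal, is the detection carrier throughout.

* MEP onset: first envelope sample above m + 2s inside the 10–60 ms
  post-stimulus search window (after a 5 ms artifact blank).
* MEP offset: first time after the envelope peak that it stays below
  m + 2s for ≥ 2 ms (the dwell rejects momentary dips).
* Amplitude: max − min of the raw signal between onset and offset;
  duration: offset − onset.
* Silent-period end: first time ≥ MEP offset at which the envelope stays
  at or above max(m − 2s, 0.1·m) continuously for ≥ 10 ms; absolute CSP =
  that time minus MEP offset.  The 0.1·m relative floor matters: the
  per-sweep SD estimate exceeds m/2 on a non-trivial fraction of sweeps,
  and without the floor the nominal m − 2s threshold falls below the
  silenced-signal level and the silent period would terminate instantly.
* Trial rejection (non-fatal, reason-coded): pre-stimulus RMS outside
  20–40% of the MVC RMS reference, no detectable MEP, or no return of
  EMG activity before the sweep ends.  The MVC reference itself is the
  conventional mean peak-to-peak over 500 ms windows (µV) plus the mean
  raw RMS used for the contraction ratio — a peak-to-peak-to-RMS ratio is not
  dimensionally comparable to a 30%-of-MVC contraction level.

Because every threshold is baseline-relative, all temporal landmarks are
exactly invariant to rescaling the sweep.  At default SNR the detector
recovers injected CSP durations with a median absolute error ≈ 2–3 ms
(well under the 5 ms acceptance bound) and a detected-vs-true slope
within [0.95, 1.05] over the 50–200 ms range; MEP amplitude is recovered
to < 1% and duration to ~±1 ms in the mean, with ~4 ms per-sweep SD
driven by threshold variability across sweeps.

Participants whose pulse block yields fewer than 50% valid trials are
dropped from inference (with the exclusion bookkeeping): their MEPs sit
at the detection threshold and the surviving "detections" are spurious.

## Inference chain

1. **Pearson family.** Pearson r with two-tailed t-based p for each of
   {CSP, rMT, MEP amplitude, MEP duration} against SSRT, judged against a
   Bonferroni-adjusted alpha 0.05/4 = 0.0125 (reported at full precision).
2. **Skipped Pearson.** Robust bivariate centre by minimum covariance
   determinant (deterministically seeded); all points projected onto the
   direction from the centre to each point; a point is an outlier if, on
   any projection, its distance from the projection median exceeds
   √χ²₍₂,0.975₎ ≈ 2.72 normalised MADs; Pearson r on the retained points.
   Significance and the 95% CI come from a percentile bootstrap over
   subject pairs (default 2000 resamples) that reruns the entire
   procedure per resample; p = 2·min(P(r* ≤ 0), P(r* ≥ 0)).  Note the
   union-over-projections rule flags ~1–3 legitimate points per clean
   27-subject sample; that is a property of the method, not a bug, and it
   is why the planted-outlier calibration is stated about the median over
   replicate datasets.
3. **LOO-CV + permutation.** For each subject, an OLS line fit on the
   other n−1 predicts the held-out SSRT; predictive power is the Pearson
   correlation between predictions and observations.  Its null
   distribution — built by shuffling SSRT (default 5000 times) and
   rerunning the whole LOO pipeline — is strongly left-shifted
   (cross-validated predictions anticorrelate with independent outcomes,
   null mean ≈ −0.2 at n ≈ 27), so p is the add-one upper-tail count
   p = (1 + #{r_null ≥ r_obs})/(n_perm + 1).  A |r|-two-tailed count
   against this asymmetric null would be nearly powerless and cannot
   reproduce published p-values of this design; the upper-tail count is
   exactly uniform under the null (verified by simulation: type-I error
   ≈ 0.045 at nominal 0.05, KS distance from uniform < 0.07).

All randomness flows from a single integer seed (NumPy `SeedSequence`,
split per participant and per pulse, so any subset regenerates stably);
identical configuration and seed give byte-identical reports.

## Problem sizes

Default analyses run at the study scale: 27 participants, 480
experimental trials and 20 pulses each.  The test suite uses that scale
for the end-to-end checks (50 seeded replicate studies for the power
property; 200 replicates for permutation calibration at 500 permutations;
10,000 go / 2,500 stop trials for estimator recovery) and smaller
configurations (12 participants, reduced bootstrap/permutation counts)
where only structural behavior is under test.

## Known limitations

* The skipped-correlation implementation follows the documented
  projection/MCD family of the published toolbox, not its exact code;
  numerical agreement with that toolbox is not claimed.  The test oracle
  is an independent brute-force reimplementation of the same definition.
* The CSP detector's ±2 SD rule is applied to the smoothed envelope; the
  original hand-scoring convention (rectified vs unrectified, baseline
  span) is unpublished, and both the baseline window and smoothing are
  config-exposed.
* The generator's coupling is linear and homoscedastic; nonlinear or
  heteroscedastic brain-behavior relationships are outside what the
  power property demonstrates.
* With measurement noise in both variables, the observed correlation at
  latent coupling 0.6 attenuates to ≈ 0.4–0.45; the end-to-end power
  statement (≥ 60% of seeded studies significant at n = 27) is about
  this attenuated effect.
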