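# Methods

## The measurement model

fTCD measures blood-flow velocity in the left and right middle cerebral
arteries.  During a language-production task, perfusion of the dominant
hemisphere increases slightly relative to the other; the laterality index
(LI) quantifies that asymmetry.  Each trial lasts 38 s: 12 s of silent
watching (used for baseline), a 10-s description period (the active task)
and 16 s of rest.  Epochs run from −12 to +26 s around the trial-onset
trigger; all windows use the half-open convention [start, end) in seconds
with onset = 0.

The per-subject procedure is:

1. **Heart-cycle integration.**  Cardiac pulsatility dominates raw CBFV.
   Systolic peaks are detected on the summed channels (more robust than a
   single channel) with a minimum inter-beat interval of 0.3 s — children's
   heart rates rarely exceed 200 bpm — and a prominence threshold of 0.25 ×
   the 5–95 percentile spread of the summed signal.  Each channel is
   replaced by its per-cycle mean at the cycle midpoint, linearly
   interpolated back onto the native grid.  On synthetic signals this
   removes > 99.9% of the power in the cardiac band.
2. **±50% flow screen.**  A trial is rejected when any velocity-scale sample
   of either channel inside its epoch leaves [0.5, 1.5] × that channel's
   whole-recording mean.  The screen inspects the *pre-integration* samples
   (against the post-integration mean): cycle averaging dilutes a brief
   probe-displacement spike below threshold, so screening the integrated
   trace would miss exactly the artifacts the rule exists for.  Trial-local
   means are deliberately not used — they would mask sustained artifacts.
3. **Normalisation.**  Each channel of each trial is rescaled to percent of
   its own mean over the full epoch (mean = 100), making the left−right
   difference a dimensionless percentage and removing between-channel
   insonation-angle differences.  Normalisation is idempotent.
4. **Baseline correction.**  The per-trial difference wave has its mean over
   [−10, −2) s subtracted.  The window ends 2 s before onset to stay clear
   of anticipatory effects and starts late enough to lie inside the
   preceding rest period.
5. **LI.**  The across-trial mean difference wave is searched over the
   period of interest (POI, 4–18 s) for the largest *absolute* value; a 2-s
   window is centred there (clamped to the epoch, ties to the earliest
   time), and the LI is the window mean.  Using the absolute peak with sign
   retained lets right-dominant subjects carry negative LIs; a signed-max
   rule could not produce them.  Per-trial LIs reuse the subject-level
   window — the one-sample t-test treats the window as a fixed measurement,
   and the subject LI then equals the mean of the per-trial LIs exactly.
6. **Classification and exclusion.**  left/right when the per-trial t-test
   is significant at α = .05 (two-tailed) and the LI is positive/negative;
   low otherwise; excluded when fewer than 9 trials survive screening.
   Behavioural rejects (utterances during baseline or rest, identified from
   video annotations) are supplied externally; the pipeline never infers
   them from the signal.

Split-half reliability runs the *complete* procedure — including an
independent peak search — separately on the odd- and even-numbered accepted
trials (1-based acquisition order) of each subject, then correlates the two
half-LIs across subjects.  Halves must be independent estimates for
split-half logic to hold.

## Equivalence testing and Bayes factors

A non-significant group difference is not evidence of equivalence.  Two
complementary analyses address this:

* **SESOI and TOST.**  The smallest effect size of interest is derived from
  the critical statistic of a reference design: t_crit = t⁻¹(1−α/2, df),
  d_crit = t_crit·√(1/n₁+1/n₂), and the raw-unit bound d_crit × pooled SD.
  The TOST runs two one-sided pooled-variance t-tests of the observed
  difference against ±bound; equivalence is declared iff both reject, which
  is provably the same event as the 90% CI lying inside the bounds (for
  α = .05).  The difference orientation is fixed by the caller's argument
  order so the directional verdicts ("can we rule out that group A is more
  right-lateralised?") are unambiguous.
* **Directional Bayes factor.**  The alternative is a half-normal prior
  B_H(0, σ) on the predicted direction — smaller effects more likely, no
  mass on the unpredicted sign.  BF₁₀ = m₁/m₀ with m₀ the likelihood of the
  observed difference at effect 0 and m₁ its marginal under the prior,
  computed by adaptive quadrature on [0, 10·√(se²+σ²)] (tolerance 1e−10)
  and cross-checked against the closed-form Gaussian-product expression
  m₁ = 2·N(obs; 0, √(se²+σ²))·Φ(μ_post/σ_post).  Because published usage
  mixes conventions, both BF₁₀ and its reciprocal are reported.  Normal and
  uniform-box priors are available for sensitivity analyses.

## The synthetic-recording generator

Each channel is `baseline × (1 + pulsatility) × (1 + response) + noise`:

* **Pulsatility**: fundamental plus two harmonics (relative amplitudes
  1 : 0.4 : 0.15) at the heart rate, scaled so the peak excursion equals
  `pulsatility_amplitude` (default 0.25, i.e. ±25% of mean — safely inside
  the ±50% screen).  This approximates a systolic/diastolic profile well
  enough to exercise beat detection without modelling hemodynamics.
* **Response**: a raised-cosine bump supported on [4, 18] s after onset
  (rising and falling half-cosines joined at the peak), peaking at 11 s by
  default — the latency observed in child language-production studies.
  Both channels share the bump (default bilateral amplitude 3% of
  baseline); the left channel carries an additional excess component that
  produces the target LI.
* **Calibration**: with bump b(t), epoch mean b̄, 2-s window mean W, and
  bilateral fraction R, normalisation and baseline correction give a
  corrected difference of 100·α·b(t)/(M_L·M_R), where M_R = 1 + R·b̄ and
  M_L = M_R + α·b̄.  Setting the window mean to the target L and solving:
  α = L·c²/(100·W − L·c·b̄) with c = M_R.  The only residual bias is the
  slight flattening of the bump peak by cycle averaging (< 0.6% of the LI).
* **Trial-to-trial LI variability** (`trial_li_sd`, default 2.5 percentage
  points): each trial's target LI is jittered around `true_li`.  Real
  per-trial LIs vary substantially — subject-level t-values of ≈ 3 over
  ≈ 14 trials with group-mean LIs near 2 imply a within-subject per-trial
  SD of roughly 2.5 — and this response-locked variability, not the white
  measurement noise, dominates the uncertainty of a subject's LI.  It also
  keeps the max-peak selection honest: under a true null the difference
  wave's noise is concentrated in the response shape, so the peak search
  performs effectively one comparison and the false-positive rate of the
  classification stays near the nominal α (≈ 6% observed over 100 null
  subjects).
* **Noise and artifacts**: white Gaussian noise per sample
  (`noise_sd`, % of baseline velocity, default 0.5); optional spikes
  (isolated samples at `spike_magnitude` × channel mean) and dropouts
  (0.5–1.5 s runs forced to 30% of the mean) at Poisson-distributed times,
  with the contaminated trial indices returned as ground truth.
* **Defaults**: 100 Hz sampling (typical of fTCD hardware exports), 20
  trials (between the task maximum of 30 and the ≈ 14 that typically
  survive screening), heart rate 90 bpm, baselines 62/58 cm/s, 14 s of
  lead-in so the first epoch's −12 s edge exists.  All randomness flows
  from explicit integer seeds; equal seeds give bit-identical recordings.

What the generator does **not** emulate: autoregulation, respiratory and
vasomotor oscillations, heart-rate variability, probe drift, bidirectional
flow, or temporally correlated (1/f) measurement noise.  Passing tests
therefore demonstrate that the pipeline's operators are correct and
unbiased under the stated signal model — not that the pipeline is robust to
every pathology of clinical recordings.

## Numerical and design choices

* Pooled-variance (Student) t throughout, not Welch: the convention of the
  summary statistics this package is designed to reproduce (df = n₁+n₂−2).
* Chi-square without continuity correction; expected counts < 5 warn but do
  not fail, matching common usage on small lateralisation tables.
* Fisher-z comparison reports one- and two-tailed p; it requires n > 3 per
  group and |r| < 1, so the group report omits it for degenerate inputs.
* Peak-window clamping: a window that would cross the epoch edge is shifted
  inside it; a window may extend beyond the POI edge (only the *peak* is
  constrained to the POI).
* Degenerate one-sample t inputs: zero variance with zero mean → t = 0,
  p = 1; zero variance with nonzero mean → t = ±∞, p = 0; a single trial →
  t undefined (NaN), category low.
* Group SD with n = 1 is reported as 0 and flagged undefined.
* `sample_group_values` rescales standard-normal draws to match a printed
  mean/SD exactly, so every summary-based statistic can be cross-checked
  against its raw-data counterpart to ≈ 1e−10.
* Recording files are delimited text with full-`repr` floats: parse → write
  → parse round-trips bit-identically (pandas is read with
  `float_precision="round_trip"`).

## Problem sizes used in validation

Parameter recovery uses 50 replicate 19-subject cohorts (li mean 2.2, SD
3.0, 20 trials, calibrated noise); classification rates use 100 simulated
subjects; the TOST/CI self-consistency property uses 1,000 random
summary/bound draws.  These sizes give Monte-Carlo standard errors well
below the tolerances they are tested against while keeping a full
validation run in the tens of seconds.

## Known limitations

* The per-trial LI noise model is response-locked; pipelines facing strongly
  autocorrelated baseline drift may show anti-conservative classification
  that these tests will not reveal.
* Whether the ±50% screen should precede or follow heart-cycle integration
  is not settled usage; this package screens pre-integration samples against
  the post-integration mean (rationale above) and documents it as a choice.
* The "10 to −2 s" baseline window is read as −10 to −2 s (a +10 s start
  would overlap the response and contradict "prior to stimulus onset").
* The hand-movement dominance denominator counts each tier's seconds as
  annotated, so bimanual movement contributes to both sides; annotation
  tiers are independent, and no fully specified convention exists.
* The minimum-duration filter for ignorable behaviours (grooming, brief
  points) defaults to 0.5 s and is configurable; it is a judgment call, not
  an empirical claim.
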