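# ftcdli

Analysis pipeline for **functional transcranial Doppler (fTCD)** studies of
language lateralisation, aimed at researchers measuring hemispheric dominance
in populations where fMRI is impractical (young children, cochlear-implant
users).  fTCD records cerebral blood flow velocity (CBFV) in the left and
right middle cerebral arteries while the participant performs a language task;
a left-right velocity difference time-locked to the task indexes hemispheric
dominance.

The package covers the full chain:

1. **Preprocessing** — heart-cycle integration (cardiac pulsatility removed by
   averaging within each detected cardiac cycle), epoching from −12 to +26 s
   around trial onsets, per-sample ±50% flow screening against the channel
   mean, per-trial normalisation to percent of epoch mean, and baseline
   correction of the left−right difference over [−10, −2) s.
2. **Laterality index (LI)** — the mean of the baseline-corrected difference
   wave in a 2-s window centred on the largest absolute difference inside the
   period of interest (4–18 s after onset):

   LI = mean<sub>t ∈ [t̂−1, t̂+1)</sub> ΔV(t),  t̂ = argmax<sub>t ∈ POI</sub> |ΔV(t)|

   Positive LI = left dominance.  Subjects are classified *left*/*right* when
   a one-sample t-test of the per-trial LIs against 0 is significant
   (two-tailed, α = .05), *low* otherwise; subjects with fewer than 9
   accepted trials are excluded.
3. **Group statistics** — one- and two-sample (pooled-variance) t-tests from
   raw values or printed summaries, Cohen's d, chi-square on lateralisation
   categories, Pearson correlation, Fisher-z comparison of split-half
   reliabilities.
4. **Equivalence testing** — SESOI derivation from a reference study's
   critical t, the TOST procedure, and a directional Bayes factor with a
   half-normal prior.
5. **Behavioural coding** — handedness laterality quotients
   (LQ = (R−L)/(R+L+Both)·100) and annotation-table arithmetic
   (hand-movement dominance, communication seconds per trial, baseline/rest
   utterance flags).
6. **Simulation** — synthetic pulsatile recordings with a known ground-truth
   LI, trial-to-trial LI variability, noise and spike/dropout artifacts, so
   every stage is verifiable without access to raw clinical data.

## Worked example

```python
from ftcdli import SimParams, simulate_recording, run_subject

params = SimParams(true_li=4.0, noise_sd=0.5, n_trials=20, seed=7)
recording = simulate_recording(params)
result, epochs = run_subject(recording)
print(f"LI = {result.li:.2f}, peak latency = {result.peak_latency:.1f} s, "
      f"t({result.df}) = {result.t:.2f}, p = {result.p:.2g}, "
      f"category = {result.category}, accepted = {result.n_accepted}")
```

prints

```
LI = 3.17, peak latency = 11.0 s, t(19) = 7.38, p = 3.7e-07, category = left, accepted = 20
```

The subject was generated with a true LI of 4.0; the measured 3.17 reflects
the trial-to-trial LI jitter of this particular draw (SD 2.5 percentage
points over 20 trials gives a subject-level SD of ≈ 0.56).  The response
peaks 11 s after trial onset, inside the 4–18 s period of interest, and the
per-trial LIs are consistently positive, so the subject is classified
left-lateralised.

The same pipeline runs from the shell:

```bash
ftcdli simulate --subjects 19 --li-mean 2.2 --li-sd 3.0 --seed 11 --out deaf/
ftcdli simulate --subjects 19 --li-mean 1.8 --li-sd 3.0 --seed 12 --out hearing/
ftcdli group deaf/ hearing/ --bound 1.9 --prior-sd 0.5 --out report.json
ftcdli equivalence --mean1 1.79 --sd1 2.95 --n1 19 --mean2 2.23 --sd2 3.02 --n2 19 \
    --derive-bound 0.05 38 20 20 2.985
ftcdli bayes --diff -0.44 --se 0.98 --prior-sd 0.5
ftcdli handedness --counts 5 3 2
```

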