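# Methods

This note documents the models, generator assumptions, numerical choices
and known limitations of `neurotrace`. Every number quoted here is either a
configuration default or is computed by the test suite / acceptance script.

## Synthetic oddball sessions

The generator emulates a three-class auditory oddball used to calibrate a
relevance decoder: 10 blocks of 60 tones (350 Hz standards at 70–80 %,
650 Hz targets at 10–15 %, 2000 Hz task-irrelevant deviants at 10–15 %),
339 ms tones, stimulus-onset asynchrony uniform in 1.5 ± 0.2 s, and a
constant 150 ms lag between the recorded marker and the true stimulus
onset (modeling a presentation-pipeline delay diagnosed post hoc; the
feature windows start at 150 ms precisely to absorb it).

Per-block class counts are drawn uniformly from the integer compositions
admissible under the stated proportion ranges (at 60 tones: 42–48 / 6–9 /
6–9). This respects the ranges in every block while long-run fractions
converge to the nominal probabilities; with ~10⁴ tones the target fraction
falls inside the exact binomial 99 % interval around 0.125 (tested).

**EEG model.** 32 channels (actiCAP 10–20 layout, FCz reference) at 500 Hz.
Each tone injects a class template into the background:

* N100-like component: −5 µV peak at 100 ms (+ lag), Gaussian sd 30 ms,
  fronto-central topography, all classes;
* P300-like component: +8 µV peak at 350 ms (+ lag), Gaussian sd 80 ms,
  parietal topography (Pz = 1.0), targets only.

The background is white Gaussian sensor noise (sd 10 µV) plus a 1/f^α
process per channel (α = 1, sd 12 µV). Nothing in the emulated study
specifies a noise model; this is the minimal model that makes single-trial
decoding non-trivial, because the 1/f component survives both the 0.3–20 Hz
band-pass and the 50 ms averaging that kill most white noise. The pink-noise
sd is the main difficulty dial: at the defaults the five-fold margin-five CV
accuracy of the decoder lands near 0.93 across seeds, comfortably above the
imbalance-aware chance level (~0.89 at ~525 binary trials, 86.7 % majority)
— the regime the acceptance suite asserts.

What the generator does **not** model: volume conduction from dipole
sources (topographies are direct weight maps), ocular/muscle artifacts,
inter-trial ERP variability in latency or amplitude, non-stationarity
across blocks, and audio itself (tones exist only as markers plus injected
waveforms). Passing tests therefore show the pipeline recovers a *known*
additive ERP from realistic colored noise — not that it would achieve any
particular accuracy on recorded EEG.

## Decoder

Windowed-means features (8 × 50 ms from 150 ms, window-major order) feed a
binary LDA with pooled covariance shrunk toward a scaled identity,
`Σ̂ = (1−γ)S + γ(trS/d)I`; γ defaults to the analytic Ledoit–Wolf estimate
on class-centered data. Class priors are equal (boundary midway between the
class discriminant means) despite the ~7:1 imbalance: the decoder must beat
an imbalance-aware chance level, which majority voting cannot.

The output is calibrated to [1, 2] via `1 + σ(k·d)` with the logistic slope
`k` fitted by maximum likelihood on the training discriminants and the
intercept pinned at zero, so a score of exactly 1.5 corresponds to the
decision boundary. A score < 1.5 means processed-as-irrelevant; exactly 1.5
counts as relevant (strict `<` rule). The slope is capped at 60 standard
deviations of the discriminant to keep near-separable fits finite.

Cross-validation uses contiguous chronological folds (default 5) with a
margin (default 5 trials) excluded from training on both sides of every
test block, guarding against temporal leakage through filter edges and slow
noise autocorrelation. `chance_threshold(n, p, α)` returns the smallest
accuracy k/n with `P(Binomial(n, p) ≥ k) ≤ α` — with p the majority-class
proportion this is the null of a guesser who is right with probability p.
On no-signal data the fitted high-dimensional LDA is empirically biased
*toward* the majority class (accuracies well above 0.5) without reaching
the majority proportion; the suite asserts it never clears the chance
threshold rather than any point value.

## Flight scenario, behavior and tracing

The shipped scenario covers a ~17.5 min segment: eight ATC instructions
(altitude/speed/heading selects), a fuel-pump caution at 4 min, a silent
fuel leak at 6 min, a TCAS traffic advisory near 7 min, four spurious
electrical cautions (auto-clearing, excluded), a fuel-imbalance caution
(excluded from analysis) and an engine-fire warning at 16:40. Ten events
per pilot are analyzable. ATC onsets are not part of the scripted timeline
and are spread evenly between the alerts; the eighth ATC slot is flagged
`reconstructed`.

**Pilot model.** Per analyzable event: omission with probability 0.14,
commission with 0.14, otherwise adequate (≈ 28 % non-adequate — the regime
of interest). Latencies are log-normal (median 8 s, log-sd 0.5), resampled
into (0.2 s, limit]. The attention flag couples behavior to EEG ground
truth: adequate responders attended with probability 1.0; lapsing pilots
attended with probability 0.5, so roughly half of all lapses are
*explainable* by inattention and the other half are attended lapses the
gate must not excuse.

**Assessment.** The 20 Hz log is scanned over `(onset, onset + 25 s]`
(boundary inclusive, configurable); the first change of each required
parameter decides — a wrong first value is a commission even if corrected
later, a change after the limit is an omission. Value matching is exact
after unit normalization, with a configurable tolerance for noisy logs.
One consequence of sampled state logs: if a lapsed earlier event left a
parameter already at a later event's target, an adequate re-entry of the
same value is invisible; the generator demotes such events to omissions in
its effective ground truth so that generated and traced categories agree by
construction.

**Tracing.** Normative: correct iff adequate. Neuroadaptive: additionally
correct when a non-adequate event scored < 1.5 (reason `gated-irrelevant`).
The gate only rescues non-adequate events, so neuroadaptive accuracy ≥
normative accuracy on any input (property-tested over random traces). The
alert-processing procedure itself is represented as a deterministic
eight-phase state machine (aural detect → decode + timer start → visual
shift → read → memorize checklist item → motor action → remaining items →
verification at exactly onset + limit); the verification step reads the
same parameter the assessor scans. Routine monitoring/thrust behavior and
workload are out of scope.

## Uncertainty accounting and statistics

For tracer accuracy `a`, epistemic uncertainty is `1 − a`. The corrected
neuroadaptive accuracy scales the added value by classifier accuracy:
`corrected = a_n + a_c (a_b − a_n)`, `μ_Aleatory = (1 − a_c)(a_b − a_n)`,
`μ_Epistemic = 1 − corrected`. This affine form is the unique correction
consistent with the three-result worked example the package reproduces
(0.72 / 0.87 / 0.88 → 0.85 / 0.15 / 0.02 at two decimals); it is exact
before rounding and satisfies `corrected + μ_Epistemic = 1` identically.

Statistics use sample (n−1) SDs and two-sided p-values throughout, no
multiple-testing correction (two tests are reported). The paired t is
computed from the difference vector directly, with the zero-variance
zero-mean case defined as (t = 0, p = 1). Cohen's d_av divides the mean
difference by the average of the two sample SDs. The 2×2 χ² is Pearson
without continuity correction by default; the Yates-corrected value is
reported alongside since either convention is defensible at N ≈ 58.

## Study orchestration and problem sizes

One integer seed is expanded into per-stage, per-pilot substreams via
`SeedSequence(seed, spawn_key=(stage, pilot))`, so growing the cohort never
reshuffles earlier pilots, and a repeated run is byte-identical. Three
classifier modes exist: `eeg` (full synthesis + decoding per pilot),
`surrogate` (the decoder emulated as a Bernoulli channel of configurable
reliability, default 0.88, acting on the attended/unattended ground truth),
and `none` (normative only — the ablation). Cohort-level sweeps (21 pilots
× 20 seeds) run in surrogate mode, which isolates the tracing and
statistics from decoder variance and runs in milliseconds per cohort; the
full EEG path is exercised by the 20-session default-scale decoder panel
and by reduced-scale pipeline tests (fewer blocks, channels and a lower
sampling rate), keeping the whole suite within a few minutes on one core.

## Known limitations

* The decoder is subject-specific; no transfer/subject-independent
  classifier is provided.
* Deviant tones are generated but never classified (binary
  standard-vs-target problem only).
* No artifact rejection, re-referencing or resampling in preprocessing.
* The scenario's ATC onsets and the pilot behavior model are synthetic
  constructions; only their statistical regime (event counts, error rates,
  response window) is matched to the emulated study.
* The corrected-accuracy formula treats classifier errors as symmetric
  across gated events; it is an accounting identity, not an error model.
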