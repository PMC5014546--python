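# Methods

`scenemeg` reimplements, end to end, the computational chain of a
regularity-based auditory change-detection experiment: synthesis of
multi-source tone-pip scenes, simulation of the evoked MEG and behavioural
data such an experiment produces, and the analysis procedures used on them.
Because no raw recordings are bundled, the synthetic-data generators are
first-class components: they define the ground truth against which every
analysis stage is validated.

## Stimuli

A scene lasts 2500-3500 ms and contains 7-8 concurrent pure-tone sources.
Carriers are drawn without replacement from a pool equally spaced on the
ERB-number scale,

    E(f) = 21.4 * log10(0.00437 f + 1),

stepping 2 ERB upward from 200 Hz until the next carrier would exceed
2800 Hz (10 carriers; the analytic inverse of E maps the grid back to Hz).
The 2-ERB spacing keeps sources a fixed perceptual distance apart and
minimises energetic masking. Each source is a train of tone-pips with a
per-source tone duration drawn once from U[22, 167] ms. In REG scenes the
silent interval between pips is also drawn once per source (U[1, 167] ms)
and then fixed, giving a perfectly periodic tone/silence cycle; in RAND
scenes every interval is drawn anew from the same distribution, so the
long-run statistics match but the pattern is unpredictable. On change
trials a new source (regular or random, with a carrier unused by the
scene) appears at a time drawn uniformly from 1000-2000 ms and the scene
always continues for exactly 1500 ms afterwards, so scene offset never
cues the change. Matched no-change stimuli reuse the identical symbolic
configuration with the appearing source deleted; both members are scaled
by the change member's peak, so their waveforms are bit-identical before
the appearance time (verified sample-for-sample in the tests).

Rendering choices the description leaves open:

* the stated 30 ms raised-cosine ramps are applied to the whole scene;
  individual pips carry 5 ms cosine ramps (22 ms pips cannot carry 30 ms
  ramps) to avoid spectral splatter;
* each original source starts with a random phase offset drawn from one
  tone/gap cycle, so source trains are desynchronised at scene onset;
  the appearing source starts exactly at its appearance time;
* the summed scene is peak-normalised to 0.9 before ramping; appearance
  times are rounded to the nearest audio sample (44.1 kHz);
* random-mode gap sequences are realised when the scene is drawn and
  stored in the symbolic spec, so a spec renders to the same waveform
  bit-for-bit on every call.

An auditory-spectrogram helper (1-ERB-wide bandpass channels on the pool
grid, smoothed envelopes) exists for visualisation and for tests that
verify band-limited properties of rendered scenes.

## Synthetic MEG

Epochs are generated directly at the 250 Hz analysis rate (channels x
time x trials; scene lock −200..800 ms, appearance lock −200..400 ms).
The 600-to-250 Hz acquisition path is out of scope, but the
filter/resample operators are exercised on synthetic high-rate signals in
the tests.

**Evoked model.** Deflections are Gaussian bumps (amplitude, latency,
FWHM); the sustained response is a raised-cosine step. Scene lock: M50 /
M100 / M200 at 80 / 110 / 200 ms (amplitudes 40 / −55 / 30 in arbitrary
field units) and a sustained level of 25 from 300 ms. Appearance lock:
deflections at 90 / 150 / 300 ms (35 / −45 / 25), with the M100 amplitude
set to 0 in the passive-listening group, mirroring the reported absence
of that component without attention. Condition effects:

* scene lock, REG: an additional sustained component of 30% of the
  sustained level, rising over 10 ms from a group-specific onset
  (436 ms passive, 476 ms active);
* appearance lock, REG: the appearance-evoked response is multiplied by
  1.22 from a group-specific onset (87 ms passive, 142 ms active) — a
  hard gate, so the planted 22% gain holds exactly at the M50 peak;
* matched no-change epochs carry no appearance-evoked components at all.

Per subject, a lognormal gain (sigma 0.2) scales all amplitudes and a
latency shift (SD 4 ms) translates the whole response, gates included.

**Sensor model.** Channels lie on a sunflower layout over the unit disc
(a flattened helmet). The auditory evoked field is deliberately
*rank-one*: all deflections share one bilateral dipolar map up to sign
(M100 is polarity-flipped, so the M50/M100 maps have mutual projection
~−1) plus a 2% private perturbation per component. This mirrors the
empirical observation that successive deflections and both conditions
show nearly identical topographies — gain-modulated common generators —
and it is what makes baseline-referenced onset detection well-behaved
(below). The regularity effect has a distinct posterior map; the
sustained response loads 0.44 on it, so the effect direction carries
reproducible evoked power and survives DSS component selection.

**Noise model.** Twenty AR(1) sources (rho 0.95) are mixed through
smooth random maps constructed orthogonal to the evoked maps (spatially
distinct generators), scaled to ~8 units per channel, plus a white
sensor floor of SD 1 — single-trial peak SNR is about 1. One background
source is special: it shares the regularity-effect map (the network
carrying the effect also produces ongoing background activity, rho 0.6,
SD 20 — the dominant background rhythm). That source undergoes
event-related desynchronisation: its amplitude halves at scene onset and
drops a further 40% after an appearance event. A configurable 2% of
trials are scaled x10 to model outlier epochs.

This noise architecture is not incidental. The onset-latency rule used in
the analysis (first deviation of the difference waveform beyond 3
baseline SDs) is only interpretable when (a) the baseline variability of
the RMS difference is set by a background direction that does not carry
pre-onset evoked activity, and (b) evoked directions are comparatively
quiet. When evoked topographies overlap the dominant background — as
they partly do in real recordings — pre-onset deflections inflate the
RMS-difference noise well beyond the signal-free baseline and the 3-SD
rule fires early. The generator therefore realises the regime in which
the method is valid; with overlapping generators the same code
reproduces the early-firing failure mode, which is a caveat to keep in
mind for real data (and a plausible account of why baseline-referenced
jackknife onsets can precede cluster onsets on real recordings).

**Behaviour.** Hit counts are binomial with per-subject logit jitter
(SD 0.5) around p = 0.85 (REG) and 0.672 (RAND) — group mean 76.1% —
and false alarms binomial at 6.25% on matched no-change trials.
Detection times are normal (SD 90 ms, subject jitter SD 30 ms) around
660 ms, 40 ms faster in REG scenes and a further 27 ms faster when the
appearing source is regular.

**What the generator does not emulate:** realistic forward models and
head geometry, eye/cardiac artifacts, continuous raw recordings,
non-stationary vigilance drifts, or overlap between evoked and
background generators (see above). Passing tests therefore demonstrate
correctness of the analysis chain under its stated assumptions, not
robustness to every property of real MEG.

## Preprocessing

* **Low-pass + resample.** Zero-phase windowed-sinc FIR whose transition
  band starts at the cutoff (half-cutoff width, Hamming design), applied
  forward-backward, followed by rational polyphase resampling. The
  passband is flat to well within 1% up to 0.8x cutoff and a 60 Hz tone
  is attenuated by far more than 20 dB at a 30 Hz cutoff. A Butterworth
  realisation was rejected because a 4th-order forward-backward filter
  at the nominal cutoff loses ~14% at 0.8x cutoff, violating the
  passband contract.
* **Epoching.** Half-open windows [t0, t1), so a 1000 ms scene epoch at
  250 Hz has exactly 250 samples and a 600 ms appearance epoch 150.
  Baseline means over [b0, b1) are removed per channel and trial;
  epochs crossing a record edge are dropped with a warning.
* **Outlier rejection.** Single pass: the per-trial score is the RMS
  over channels and time of (trial − across-trial mean); trials beyond
  mean + 3 SD of the scores are discarded. The decision is
  scale-invariant. Being single-pass, the rule *masks* when outliers
  exceed roughly 10% of trials (they inflate the threshold enough to
  survive); at the 96-trials-per-condition scale used here the
  probability of that regime is negligible, but it is a known limitation
  at small trial counts.
* **DSS.** Whiten by PCA on the pooled single-trial covariance
  (discarding eigenvalues below 1e-6 of the maximum), then
  eigen-decompose the whitened covariance of the trial average.
  Eigenvalues are reproducibility ratios in [0, 1]; components are
  ranked by them. The model is fitted once per subject on the pooled
  scene-locked epochs (bias window matching the scene epoch) and its top
  two components are used to denoise both locks. Back-projection uses
  the pseudo-inverse patterns; keeping all components reproduces the
  input to 1e-8 and the kept-subspace projection is idempotent.

## Statistics

* **RMS time-course:** v(t) = sqrt(mean over sensors of x(c, t)^2) — a
  polarity-free magnitude summary.
* **Cluster-based permutation test.** Per-sample paired (or two-sample)
  t statistics; samples beyond the two-tailed critical value at the
  height threshold (p < 0.05) form temporally contiguous clusters;
  the cluster statistic is the sum of |t| (mass); the null is the
  maximum cluster statistic over permutations (sign flips of paired
  differences, or group-label shuffles), pooling positive and negative
  clusters. FWE p-values use (1 + exceedances) / (1 + n_perm), so they
  are never zero. For paired designs all 2^n sign patterns can be
  enumerated; the tests verify the Monte-Carlo null against that exact
  enumeration at n = 8. Under the no-effect simulation the rejection
  rate is confirmed to sit inside the 95% binomial interval around 0.05
  over 200 replicates.
* **Jackknife onset latency.** For each leave-one-participant-out
  subsample, the difference waveform is grand-averaged; the onset is
  the first post-zero latency at which it deviates from its baseline
  mean (−200..0 ms) by more than 3 baseline SDs, linearly interpolated
  between samples so latencies are not quantised to the 4 ms grid.
  The corrected standard error is the jackknife SE inflated by (n−1),
  equivalently SD(subsample latencies) x (n−1)/sqrt(n). Subsamples that
  never cross are flagged; a completed estimate requires all to cross.
* **Corrected two-sample latency test.** t = difference of subsample
  means over the root-sum-square of the corrected SEs, df = n1+n2−2.
  A zero-variance comparison with unequal means is returned as +-inf
  and flagged degenerate rather than silently reported.
* **Channel subsets.** Channels are ranked by their mean signal in a
  chosen window (e.g. the appearance-evoked M50, 72-112 ms) on the
  condition-pooled group average; the most positive and most negative
  subsets are averaged per subject with polarity preserved.
* **Behaviour.** d' = z(hit rate) − z(false-alarm rate) with rates
  clamped to [1/(2N), 1 − 1/(2N)]; detection time is key-press minus
  appearance time averaged over hit trials. The 2x2 repeated-measures
  ANOVA (scene structure x appearing-source structure) is computed by
  the exact contrast identity for two-level factors (each F(1, n−1) is
  the squared paired t of the corresponding contrast; cross-checked
  against an independent implementation in the tests). Within-subject
  SEs use subject-mean centring with the small-sample correction.

## Numerical and design choices

* All randomness flows through `numpy.random.Generator`; the pipeline
  spawns independent per-stage child streams from one master seed via
  `SeedSequence.spawn`, so stimuli, sensor noise, behaviour and
  permutations are independently reproducible and every artifact is
  stamped with the seed and a hash of the resolved configuration.
* Epoch windows are half-open; all sample counts follow from that.
* The permutation p-value convention, the two-tailed height threshold,
  and the pooled positive/negative max-statistic null are as stated
  above; ties in the null are counted conservatively (>=).
* Degenerate inputs: empty scenes render silence; constant channels
  baseline to zero; identical trials yield no outliers; all-zero
  difference waveforms raise a flagged onset error.
* Problem sizes in the validation suite are chosen for a desktop run:
  group sizes 14 + 13 as in the modelled design, 32 channels
  (configurable to 274), 96 trials per condition for onset-recovery
  runs, 200 replicates x 500 permutations for the calibration study.

## Known limitations

* The onset rule's validity depends on the spatial separation of evoked
  and background generators (discussed above); the package makes that
  assumption explicit rather than hiding it.
* The jackknife SE for threshold-crossing latencies is only
  approximately calibrated; the null rejection rate of the two-sample
  latency test is verified empirically to stay near nominal under the
  default generator, but threshold-crossing statistics are not smooth
  functionals and the approximation degrades if the crossing is razor
  sharp relative to between-subject variability.
* The single-pass outlier rule masks heavy contamination (above).
* Cluster formation is one-dimensional (time only); RMS collapses the
  sensor dimension, so no channel-adjacency clustering is provided.
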