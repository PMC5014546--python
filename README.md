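# scenemeg

Synthesis and analysis pipeline for **regularity-based auditory change
detection**: artificial acoustic "scenes" of concurrent tone-pip sources,
synthetic evoked-MEG and behavioural data with a known planted effect
structure, and the statistical machinery used to analyse such experiments
— RMS evoked time-courses, cluster-based permutation tests, jackknife
onset-latency estimation, DSS denoising, and signal-detection statistics.

## The science in brief

In the modelled paradigm, listeners hear 2.5-3.5 s scenes of 7-8
concurrent pure-tone sources whose carriers are equally spaced on the
ERB-number scale, E(f) = 21.4 log10(0.00437 f + 1) (2-ERB steps between
200 and 2800 Hz). Sources repeat tone-pips either with a fixed
tone/silence cycle (REG) or with random silent intervals drawn from the
same distribution (RAND). On half the trials a new source appears
1000-2000 ms into the scene; the task (for an active group) is to detect
it. Temporal regularity of the scene improves detection, raises the
sustained evoked response from ~400 ms after scene onset, and boosts the
appearance-evoked response (+22% at the first deflection in passive
listeners), with the regularity benefit arriving later under active
attention.

The package provides:

* `scenemeg.erb`, `scenemeg.scenes` — ERB-scale carrier pools, symbolic
  scene specifications that render deterministically to audio, matched
  change/no-change pairs that are bit-identical before the appearance
  time, auditory spectrograms, balanced trial sequencing;
* `scenemeg.simulate` — multichannel evoked-MEG epoch generators
  (channels x time x trials) with M50/M100/M200 deflections, a sustained
  component, group-specific REG-vs-RAND effect onsets, spatially
  structured AR(1) sensor noise, outlier trials, and trial-level
  behavioural tables (hits, false alarms, detection times);
* `scenemeg.preprocessing` — zero-phase low-pass filtering and
  resampling, half-open epoching with baseline correction, 3-SD
  outlier-trial rejection, and denoising source separation (DSS:
  whitening on the pooled covariance, eigen-decomposition of the
  trial-average covariance, reproducibility-ranked components);
* `scenemeg.stats` — RMS-across-sensors time-courses; cluster-based
  permutation tests with max-statistic family-wise error control (sign
  flips for paired designs, exhaustive enumeration available); jackknife
  onset latencies with the (n-1) standard-error correction and the
  corresponding corrected two-sample test; polarity-preserving channel
  subsets; d' = z(hit) − z(false alarm) with extreme-rate clamping; 2x2
  repeated-measures ANOVAs;
* `scenemeg.pipeline` / `scenemeg.cli` — a seeded, configuration-driven
  orchestration of the whole chain with machine-readable reports.

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.

## Worked example

Run the full pipeline — synthesize a trial manifest, simulate two
subject groups, preprocess (outlier rejection + DSS), and analyse — from
a small config:

```yaml
# cfg.yaml
simulation:
  n_passive: 10
  n_active: 10
  n_channels: 32
  trials_per_cond: 64
stats:
  n_perm: 1000
```

```bash
scenemeg run-all --config cfg.yaml --out out/ --seed 2026
scenemeg report out/report.json
```

prints

```
seed=2026  config=64c20e136e776002
[Active] appearance_reg_vs_rand: 1 significant cluster(s) 140-392 ms (p=0.0030); onset 138 +/- 1 ms
[Active] nochange_reg_vs_rand: 0 significant cluster(s)
[Active] scene_reg_vs_rand: 1 significant cluster(s) 476-796 ms (p=0.0020); onset 480 +/- 1 ms
[Passive] appearance_reg_vs_rand: 2 significant cluster(s) 88-124 ms (p=0.0240), 212-388 ms (p=0.0030); onset 84 +/- 2 ms
[Passive] nochange_reg_vs_rand: 0 significant cluster(s)
[Passive] scene_reg_vs_rand: 1 significant cluster(s) 440-796 ms (p=0.0040); onset 442 +/- 2 ms
scene onset Passive vs Active: t(18)=-16.63, p=0.0000
appearance onset Passive vs Active: t(18)=-29.08, p=0.0000
```

Reading this against the planted ground truth: the sustained REG > RAND
scene effect was injected at 436 ms (passive group) and 476 ms (active
group) — the cluster test finds clusters from 440 / 476 ms and the
jackknife estimates 442 +/- 2 and 480 +/- 1 ms. The appearance-locked
REG > RAND gain was gated at 87 / 142 ms — recovered at 84 +/- 2 and
138 +/- 1 ms, and the corrected two-sample test confirms the group
difference. The matched no-change epochs, which carry no appearance
response, correctly yield no clusters. The behavioural block of the same
report gives condition-wise d' (REG ~2.6 vs RAND ~2.0 in this run) and
detection times showing the ~30 ms advantage for regular appearing
sources, with their repeated-measures F tests.

Individual stages are also available as `scenemeg synth-stimuli`
(renders WAV scenes with JSON sidecars and a CSV manifest),
`scenemeg simulate` (HDF5 epoch container + behaviour CSV) and
`scenemeg analyze`, or directly as library calls.

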