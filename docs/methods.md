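# Methods

## Scope and model

`icohnet` estimates upper-limb motor function (UL-FMA, 0–66) in chronic stroke
from task EEG.  The measurement model has three layers:

1. **Sensor-space functional connectivity.**  Per analysis window and trial,
   a single-segment Hann-tapered Fourier transform at 1 Hz resolution gives
   X_i(f); the cross-spectrum averages over trials,
   S_ij(f) = (1/N) Σ_n X_i^(n)(f) X_j^(n)*(f).  Coherency normalizes by the
   auto-spectra, C_ij(f) = S_ij(f)/√(S_ii(f) S_jj(f)) (the standard
   normalization; it is recorded in output metadata because variant
   definitions circulate), and the connectivity measure is the imaginary part,
   iCOH = ℑ{C_ij(f)}, averaged over half-open band intervals
   (alpha 8–13 Hz, beta 13–30 Hz by default; configurable).  A zero-lag common
   source contributes only to ℜ{C}, so iCOH is structurally insensitive to
   volume conduction — the package tests this property explicitly rather than
   assuming it.
2. **Graph summary.**  iCOH matrices are proportionally thresholded: the
   round(k·n(n−1)/2) largest |iCOH| pairs become edges of a binary graph
   (ties broken toward the lower channel-index pair, deterministically).
   Metrics are the standard binary forms: global/nodal efficiency with
   unreachable pairs contributing 0, degree centrality, local efficiency as
   the efficiency of the neighbor-induced subgraph (the weighted form's cube
   root collapses on binary graphs), and the nodal clustering coefficient
   2t_i/(k_i(k_i−1)) with C_i = 0 for k_i < 2.  Shortest paths are unweighted
   (BFS per node).  Thresholding is per subject and window.
3. **Outcome regression.**  Candidate features are the task-related percent
   change (post−pre)/pre×100 of DC, LE and CC per motor-area channel plus the
   ERD percent per channel; stepwise selection over a quadratic scope
   (linear + squared + pairwise products, intercept always included,
   forward-first from the intercept-only model, partial-F entry and removal
   at α = 0.05, no term hierarchy enforced) fixes a term set, and
   leave-one-out refits report RMSE (both /n and /(n−1) denominators),
   R²/adjusted R² and the actual-vs-predicted Pearson correlation.

## Preprocessing conventions

- Band-pass 1–80 Hz with a zero-phase windowed-sinc FIR (MNE's hamming
  design, ~53 dB stopband).  A low-order IIR cannot deliver the ≥40 dB
  out-of-band suppression this pipeline treats as its filtering contract, so
  the FIR is the package's choice; all filter parameters are visible in the
  function signature and no claim is made that they match any particular
  historical analysis.
- Polyphase resampling to 256 Hz; epochs −2…+5 s around the cue; trials whose
  window would cross a recording edge are dropped with a logged warning.
- Common average reference, then hemispheric flipping: when the performing
  (or affected) hand is left, each lateral channel swaps with its homolog
  (C3↔C4 etc., midline fixed), so the left hemisphere is always contralateral
  to the performing hand.  The homolog map for the 64-channel layout ships as
  a data file.
- Analysis windows: pre −1…0 s, post 0.25…1.25 s (the post window skips the
  movement-preparation latency after the cue).  All windows are half-open
  [start, end) in 0-based sample coordinates.
- An artifact-cleaning hook exists between epoching and re-referencing; the
  default is a pass-through, since the synthetic data carry no muscle
  artifacts and cleaning belongs to external tools.

## Synthetic cohorts

The generator emulates the study protocol: 64 channels at 256 Hz, 42 trials,
epochs −2…+5 s, a stroke and a control group (12 subjects each by default;
strokes alternate affected hand, controls perform with the left hand — a
`hand_policy="all_right"` variant keeps planted effects on their nominal
channels for channel-anchored recovery studies).

- *Background*: white noise (1 µV SD) plus a 1/f-shaped component (0.3 µV)
  per channel and trial, plus an optional common zero-lag broadband source
  (volume conduction, default on) with random per-channel gains.
- *Planted edges*: one latent narrow-band oscillator projected into channel i
  directly and into channel j with phase delay φ, gated to the pre/post/both
  window; amplitude = 2 µV × coupling strength (0–1).  φ = 0 reproduces pure
  instantaneous mixing and must yield null iCOH.
- *ERD*: a sustained narrow-band oscillator whose post-window amplitude is
  solved against the measured background so that post/pre band power ≈ the
  requested ratio (baseline oscillator power = 4× background band power).
  The −0…0.25 s gap is bridged with a linear amplitude ramp.
- *Between-subject variability*: effect sizes are multiplied by a log-normal
  factor (default 0.2 relative SD; recovery studies here use 0.3) — the
  magnitude of real between-subject network variability is not known from the
  source data, so it is an explicit free parameter.
- *Outcome*: UL-FMA = intercept + Σ coef × true feature value + N(0, σ),
  clipped to [0, 66].  `planted_truth` returns the noise-free feature values
  and outcomes for parameter-recovery tests without synthesizing signals.
- Determinism: all draws flow from `SeedSequence(seed)` with per-subject
  spawn keys; identical spec + seed is bit-identical.

What the generator does **not** emulate: realistic head-model/leadfield
mixing, EMG/EOG artifacts, non-stationary background spectra, or correlated
multi-edge network topologies.  Passing tests therefore demonstrate that the
pipeline recovers the structures it is designed to measure under controlled
conditions — not that it would recover them at the same SNR in clinical
recordings.

## Statistical procedures

- Wilcoxon rank-sum: exact enumeration (via the equivalent Mann-Whitney U)
  when both n ≤ 10 and no ties; tie-corrected normal approximation with
  continuity correction otherwise.
- Spearman: exact permutation p for n ≤ 9 without ties; t-approximation
  otherwise.
- ANCOVA: OLS of post ~ group + pre with Type II sums of squares; the F of
  the group factor is reported.  Its type-I error is verified at 0.05 ± 0.02
  over 2000 null simulations.
- Threshold scan: fractions 1–90% in 1% steps (the step is a package choice);
  per fraction, the rank-sum p of the group difference in task-related global
  efficiency; the selected threshold is the minimum-p fraction among those
  with p < 0.05, with **no multiple-testing correction** — matching the
  published selection rule.  **Caveat**: with ~90 partially correlated
  thresholds, the family-wise probability of selecting *something* under the
  null is large (empirically ~60% at 12 channels and 4+4 subjects, and
  essentially 1 at 64 channels and 12+12); a selected threshold is therefore
  not by itself evidence of a group difference.  The positive control is a
  planted group difference whose recovered direction must match the plant.
- Stepwise selection shares the same multiplicity property: minimum-p entry
  over an m-term scope admits a spurious term with probability
  ≈ 1−(1−α)^m under the null.  The calibration of the underlying partial-F
  p-values is tested with a scope-Bonferroni α; the default procedure remains
  uncorrected, as published, and should be read with that optimism in mind
  (the bootstrap stability analysis is the intended guard).
- Bootstrap stability: each of 1000 runs holds one subject out (cycling),
  resamples the remaining n−1 with replacement, reruns stepwise, and records
  the selected terms; reported as per-term selection frequencies.  This is
  one concrete reading of "leave-one-out bootstrapping"; a fully nested
  selection-inside-each-fold mode is available separately in
  `loo_predict`-style workflows by refitting term sets per fold.
- Leave-one-out prediction fixes the term set from selection on the full
  sample (as published; this induces selection optimism) and refits only the
  coefficients per fold.

## Numerical choices and degenerate inputs

- Frequency bands are half-open [low, high) so adjacent bands do not share a
  bin.  Empty bands, zero auto-spectra (named channel and frequency),
  single-trial windows, single-channel referencing, pre = 0 contrasts,
  constant Spearman inputs, constant LOO predictions, and singular LOO folds
  (named fold) are all hard errors.
- Proportional-threshold tie-break: stable sort on (−|w|, i, j).
- Edge counts use round-half-up of fraction × n(n−1)/2.
- RMSE is reported under both /n and /(n−1) conventions because the bundled
  prediction table's printed RMSEs are not consistent with a single
  convention; the actual-vs-predicted correlation is the canonical metric.
- Table verification compares means/SDs at the printed precision (±1.5 of the
  last printed digit) and correlations at 4 decimals (±1.5e-4), since
  predictions are themselves printed rounded.

## Problem sizes in the test and acceptance suites

Monte-Carlo suites run on reduced cohorts chosen to keep the full run on a
single CPU comfortably short while preserving the tested contrast: 8–16
channels, 4–16 subjects per group, epochs −1.1…+1.35 s (just covering both
analysis windows), 42 trials always.  Counts that define a procedure are kept
at full size: 200-cohort iCOH null, 2000 ANCOVA null simulations, 1000
bootstrap runs, exhaustive graph enumeration up to 6 nodes.  The
parameter-recovery study plants an ERD of ratio 0.5 on one channel with 0.3
relative between-subject spread and outcome UL-FMA = 60 + 0.4 × ERD% +
N(0, 0.5); ERD estimation error is ~3% absolute, so coefficient estimates on
*estimated* features carry a small errors-in-variables attenuation — the
unbiasedness check of the regression machinery runs on the noise-free truth
features, and the estimated-feature route is checked for selection, LOO
error floor, and bootstrap stability.

## Known limitations

- Sensor-space iCOH rankings use |iCOH|; the sign (lead/lag direction) is
  recorded but not used for topology.
- The uncorrected threshold scan and stepwise entry are optimistic under the
  null (above); both follow the published procedure deliberately.
- The EDF export is plain EDF (16-bit, one data record per trial); round
  trips quantize amplitudes to ~1/65536 of the per-file physical range.
- No source reconstruction, directed connectivity, weighted-path metrics, or
  artifact simulation.
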