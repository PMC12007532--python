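# Methods

This note documents the models, parameter choices, and numerical
decisions behind the package, and what the synthetic-data tests do and do
not establish about real recordings.

## The closed-loop model

The online chain treats the feedback computation as a per-trial pipeline
over a 10 Hz two-chromophore stream. All filters are causal (2nd-order
Butterworth high-pass at 0.01 Hz, low-pass at 1 Hz, then a 50-sample
moving average), because a real-time system cannot be zero-phase; the
offline robustness filters (3rd-order Butterworth, 0.01–0.09 Hz bandpass)
are zero-phase forward–backward, where lag matters and causality does
not. Causal stages are initialized at steady state with respect to the
first sample (`scipy.signal.sosfilt_zi`); with zero initial conditions
the high-pass startup transient decays over minutes and systematically
contaminates the first blocks of every session, which a session-level
learning metric then misreads as change over time.

Per-trial CBSI parameters come from the final 30 s of the preceding
no-regulation phase; when that phase is only 25 s long the whole phase is
used. The CBSI premise is that neural HbO and HbR are tightly
anticorrelated while motion moves both chromophores in the same
direction, so (X − αY)/2 preserves neural signal and cancels
positively-correlated artifacts. Degenerate windows are guarded rather
than fatal: a flat HbR window sets α = 1, a flat baseline window replaces
sd with machine epsilon, and both are flagged on the trial trace and in
the session log.

Interpretation choices where the protocol description is underdetermined,
all fixed here and exposed as configuration where reasonable:

- **md** in the baseline normalization is read as the *median* of the 5 s
  window (mean available via `md_interpretation="mean"`).
- The normalization window is the *offset-corrected* HbO baseline
  (CBSI assumes offset-corrected inputs; subtracting the raw level would
  re-introduce the DC the offset correction just removed).
- Trial summaries (median/SD per 30 s trial) are computed on the smoothed
  feedback signal — the quantity the display shows — identically online
  and offline, making the offline replication variant exactly equal to
  the online engine.
- Display smoothing is a restarting linear ramp: each change of target
  starts a fresh 1 s (10-update) linear ramp from the currently displayed
  value.
- Feedback values are clamped to [0, 10]; image indices round half-up;
  the reward comparison is strict (> level 5); the k-adaptation criterion
  is ≥ 75% of regulation samples pooled over the run's six trials.
- Run success is the median of the six trial medians, strictly positive
  (up) or negative (down); exact zeros count as unsuccessful. ">50%
  successful runs" over 12 runs means ≥ 7. Decreasing trial-SD (negative
  slope / negative last-vs-first) counts as variability improvement in
  both groups.
- Quality control computes CoV on series including their mean level
  (CoV of a zero-mean series is undefined; such channels are routed to
  manual review, not auto-excluded). A flat line is ≥ 10 bitwise-identical
  consecutive samples — device quantization makes exact repetition the
  meaningful signature. "Six neighboring trials" means up to three on
  each side, truncated at the sequence edges. Outlier statistics are
  computed once on the original trial (no iterative re-estimation).

## The synthetic-data generator

The generator emulates the study conditions, not a biophysical forward
model. It starts at chromophore concentrations (as the acquisition device
exports them) and superimposes, per channel:

- a neural response only in the feedback channel: the regulation boxcar
  of each run, scaled by that run's true amplitude, convolved with a
  canonical double-gamma HRF (peak at 6 s, undershoot near 16 s, peak
  normalized to 1; the convolution is rescaled so a sustained block
  plateaus at the run amplitude);
- shared systemic physiology: sinusoids at 1.1 Hz (cardiac, 66 bpm),
  0.3 Hz (respiration) and 0.1 Hz (Mayer waves) with amplitudes 0.2, 0.3
  and 0.5 signal units and per-participant random phases. The cardiac
  rate is deliberately not exactly 1 Hz, which sits on a spectral null of
  the 5 s moving average and would vanish in the device filter alone;
- linear drift (0.02 units/min) and white noise (sd 0.05);
- HbR as −0.5 × the neural HbO (exact anticorrelation by construction)
  plus a 0.3× share of the systemic physiology and independent noise.
  Giving HbR *no* structured variance would make the CBSI sd-ratio α
  explode unphysically; real HbR carries systemic oscillations too;
- injectable artifacts: motion spikes (positively correlated across
  chromophores, 0.5× in HbR), flat lines, and high-variance segments.

Default regulation trajectories define the two scenarios: upregulation is
a constant 0.5 units across all 12 runs (activation that is sustained but
does not grow); downregulation declines linearly from +0.5 to −0.25
(initial stimulus-driven activation that disappears and reverses with
training). The absolute scale is arbitrary — no published signal-unit
magnitudes exist for this response — and was chosen once so that success
and failure scenarios are separable through the full chain, not to match
physiology.

Behavioral tables reproduce the blocked Posner design (six invalid blocks
of 12 valid + 8 invalid trials, six valid blocks of 20 valid trials;
240 trials, 80%/20% cue validity) and a 4-trials-per-block PT/NPT
director task (six blocks per condition, at most two consecutive blocks
of one condition). Reaction times are shifted lognormals (shift 150 ms)
moment-matched to the configured cell means and SDs; the default cells
are the published baseline values, with post-assessment cells derived by
shifting each condition cell by the group's across-condition pre/post
change (up −17 ms, down +15 ms; vPT −130 ms in both groups) and rescaling
SDs by the group's across-condition SD ratio. Accuracies are Bernoulli
per (task, condition, time); vPT accuracy rises by 0.025 after training,
capping at 1 (the task shows a ceiling effect).

Every participant receives their own pseudo-random 25/30 s no-regulation
jitter (balanced three of each per run), as in the protocol. Sharing one
schedule across a simulated cohort turns the jitter into a fixed
run-specific effect that does not average out and biases cohort-level
learning metrics.

What the generator does **not** emulate: optical densities or the
Beer–Lambert inversion, anatomy-dependent channel sensitivity,
non-stationary physiology (heart-rate variability, task-evoked systemic
responses), between-participant variance in behavioral cell means, serial
RT dependencies, and task-correlated motion. Passing tests therefore show
that the pipeline computes its definitions correctly and recovers known
ground truth under realistic noise — not that the protocol's scientific
conclusions transfer to any particular real dataset.

## Problem sizes and known behavior

Cohort analyses use single-channel recordings (the closed loop reads only
the feedback channel; the 2×22 montage matters only for QC and the
common-average-reference variant). The parameter-recovery checks use 20
declining-amplitude participants, 100 replicates of 12 flat-amplitude
participants for the null check, and 100 replicates of 25 participants
per group for the behavioral sign-recovery check; the analysis drivers
use 10 participants per group.

Two quantitative behaviors worth knowing:

- A small positive bias (~0.05 normalized units, ~2% of typical trial
  medians) remains in last-vs-first under a flat scenario: the session's
  first block has no preceding regulation-block HRF carry-over in its
  baseline window, so run 1 sits marginally lower. This is a protocol
  artifact the simulation reproduces faithfully.
- The three offline variants are *not* on a common scale: each normalizes
  to its own baseline-window SD, and the bandpass/CAR variants shrink
  baseline variability, inflating their normalized medians. Comparisons
  across variants should therefore be directional or relative, never of
  raw magnitudes.

## Statistical utilities

Group inference is deliberately limited to the t-test family: one-sample
t against baseline with d = m/sd, paired t on session differences with
d = mean(Δ)/sd(Δ), and Welch's unequal-variances t between groups.
The sensitivity utility solves for the minimal detectable d of an
independent-samples t-test by root-finding on the noncentral t
distribution (noncentrality d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2); sidedness
is a parameter, defaulting to one-sided. Spearman correlations use exact
tie-corrected ranks with Bonferroni adjustment min(1, m·p) over a
declared family size. The reorienting effect is signed invalid − valid,
so positive values are attention costs; per-participant harmonic means
are computed first and group statistics operate on those.
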