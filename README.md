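# fnirs-nfb

A closed-loop fNIRS neurofeedback pipeline, implemented end to end and
exercised on synthetic data with known ground truth.

The scientific setting: participants learn to up- or downregulate the
oxygenated-hemoglobin (HbO) signal of a single fNIRS channel over the right
temporoparietal junction (rTPJ) across a 12-run training (2+4+4+2 runs over
four days, six 30 s regulation trials per run), guided by a 0–10 avatar
display updated every 100 ms and a monetary reward (0.01 €/s above display
level 5). The package is aimed at researchers who want to prototype, test,
or re-analyze such closed-loop protocols without access to recorded human
data: every stage — signal generation, real-time processing, quality
control, success metrics, behavioral analysis — is a tested library
function.

## The computation at its core

Each regulation trial is processed online as:

1. **Device filtering** — causal 0.01 Hz high-pass, 1 Hz low-pass, 5 s
   moving average, per channel and chromophore.
2. **CBSI motion correction** — with offsets and the noise-amplitude ratio
   α = sd(HbO)/sd(HbR) estimated from the last 30 s of the preceding
   no-regulation phase:

   X(t) = HbO(t) − mean(HbO[−30 s, 0 s]),  Y(t) likewise for HbR,
   X_corr(t) = (X(t) − α·Y(t)) / 2

3. **Baseline normalization** — to the last 5 s of the no-regulation phase:
   signal(t) = (X_corr(t) − md(HbO[−5 s, 0 s])) / sd(HbO[−5 s, 0 s]),
   with md read as the median (mean available by configuration).
4. **Display mapping** — value(t) = 10·signal(t)/(k·T), negated for the
   downregulation group, clamped to [0, 10] and quantized to 11 avatar
   images; reward accrues at 0.01 €/s strictly above level 5. T is the
   individual threshold from the pre-assessment activation contrasts
   (mean of invalid−valid and PT−NPT; positive contrast if the mean is
   negative; default 1 if both are negative), k starts at 0.25 and grows
   by 0.25 after any run spent ≥ 75% of regulation time above level 5.

Offline, channels are screened (CoV > 10% in either chromophore,
chromophore CoV difference > 5%, flat line ≥ 1 s), bad trials are replaced
by the mean of their six neighbors, on-trial outliers beyond 3 SD by the
last retained observation, and two robustness re-analyses repeat the chain
with a stringent 0.01–0.09 Hz bandpass or a left-hemisphere common average
reference inserted before CBSI. Success is graded per run (median of the
six trial medians positive/negative), per participant (> 50% successful
runs; regression slope over runs; last-vs-first session change; the same
measures on trial SDs), and per group (one-sample, paired, and Welch
t-tests with Cohen's d).

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the two
built-in scenarios (sustained upregulation vs an initial activation that
declines and reverses):

```bash
python analysis/01_simulate.py
python analysis/02_closed_loop.py
python analysis/04_success_metrics.py
```

which prints, among other output:

```
schedule: 12 runs, 72 regulation trials, 36 min total regulation time
up: earned 15.50 EUR total, mean 21.5 s/trial above threshold, k ended at 1.25
down: earned 7.41 EUR total, mean 10.3 s/trial above threshold, k ended at 0.5
up: regulation vs baseline M = 1.66 (t = 28.52, p = 3.9e-10); last-vs-first diff +0.27 (p = 0.26)
down: regulation vs baseline M = 0.47 (t = 7.57, p = 3.4e-05); last-vs-first diff -2.49 (p = 3.6e-08)
```

Reading this: the upregulation participant stays above the reward
threshold for most of each trial, so k climbs and earnings accumulate;
the downregulation participant starts activated and loses the reward as
the true amplitude declines. At the cohort level both simulated groups
show positive regulation against baseline, but only the downregulation
group changes from the first to the last session — exactly the
dissociation the success-measure hierarchy is designed to detect.

The same stages are exposed as a CLI (`nfb simulate | feedback | qc |
reanalyze | metrics | behavior | report`) for running single stages on
files.

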