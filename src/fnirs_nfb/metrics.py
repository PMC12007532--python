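"""Neurofeedback success measures and group-level statistics.

Implements the success-measure hierarchy: maintenance of regulation
against baseline (per-run success, one-sample t-test), improvement in
amplitude (regression slope over runs, last-vs-first session change) and
in variability (the same measures on the per-run SDs), individual
classifications, plus the sensitivity-analysis utility (minimal
detectable effect of an independent-samples t-test via the noncentral t
distribution) and Spearman correlations with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Per-run and per-participant summaries
# ---------------------------------------------------------------------------

@dataclass
class RunSummary:
    """Per-trial medians and SDs of one run's feedback signal."""

    run_index: int
    session_index: int
    trial_medians: tuple
    trial_sds: tuple
    run_mean_median: float
    run_mean_sd: float
    successful: bool


@dataclass
class ParticipantSummary:
    """Individual-level success classification over a full training."""

    direction: str
    n_runs: int
    n_successful_runs: int
    classified_successful: bool
    slope: float
    slope_successful: bool
    last_vs_first: float
    last_vs_first_successful: bool
    sd_slope: float
    sd_slope_successful: bool
    sd_last_vs_first: float
    sd_last_vs_first_successful: bool


def summarize_run(trial_signals: list, direction: str,
                  run_index: int = 1, session_index: int = 1,
                  n_trials: int = 6) -> RunSummary:
    """Summarize one run from its per-trial feedback-signal series.

    A run counts as successful when the median of the per-trial medians is
    strictly positive (upregulation) or strictly negative (downregulation);
    an exact zero counts as unsuccessful.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(trial_signals) != n_trials:
        raise ValueError(
            f"expected {n_trials} trials per run, got {len(trial_signals)}"
        )
    medians = tuple(float(np.median(np.asarray(s, float))) for s in trial_signals)
    sds = tuple(float(np.std(np.asarray(s, float), ddof=1)) for s in trial_signals)
    med_of_med = float(np.median(medians))
    success = med_of_med > 0 if direction == "up" else med_of_med < 0
    return RunSummary(
        run_index=run_index, session_index=session_index,
        trial_medians=medians, trial_sds=sds,
        run_mean_median=float(np.mean(medians)),
        run_mean_sd=float(np.mean(sds)),
        successful=bool(success),
    )


def runs_from_traces(traces, direction: str,
                     run_to_session=None) -> list[RunSummary]:
    """Group closed-loop traces by run and summarize each.

    ``run_to_session`` maps run index to session (day); defaults to the
    2+4+4+2 layout of a full 12-run training.
    """
    if run_to_session is None:
        run_to_session = {r: d for r, d in zip(
            range(1, 13), [1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 4, 4])}
    by_run: dict[int, list] = {}
    for tr in traces:
        by_run.setdefault(tr.run, []).append(tr.feedback_signal)
    return [
        summarize_run(sigs, direction, run_index=r,
                      session_index=run_to_session.get(r, 1),
                      n_trials=len(sigs))
        for r, sigs in sorted(by_run.items())
    ]


def runs_from_trial_table(table, direction: str,
                          run_to_session=None) -> list[RunSummary]:
    """Build run summaries from a per-trial summary table.

    ``table`` has one row per regulation trial with columns ``run``,
    ``trial_median`` and ``trial_sd`` (the output of the closed loop or of
    an offline re-analysis variant).  Run success follows the same rule as
    :func:`summarize_run`.
    """
    if run_to_session is None:
        run_to_session = {r: d for r, d in zip(
            range(1, 13), [1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 4, 4])}
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    out = []
    for r, grp in table.groupby("run"):
        medians = tuple(float(v) for v in grp["trial_median"])
        sds = tuple(float(v) for v in grp["trial_sd"])
        med = float(np.median(medians))
        success = med > 0 if direction == "up" else med < 0
        out.append(RunSummary(
            run_index=int(r), session_index=int(run_to_session.get(int(r), 1)),
            trial_medians=medians, trial_sds=sds,
            run_mean_median=float(np.mean(medians)),
            run_mean_sd=float(np.mean(sds)),
            successful=bool(success),
        ))
    return sorted(out, key=lambda s: s.run_index)


def ols_slope(y, x=None) -> float:
    """Unweighted OLS slope of y against x (default 1..n)."""
    y = np.asarray(y, dtype=float)
    x = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, float)
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def classify_participant(runs: list[RunSummary], direction: str,
                         allow_partial: bool = False) -> ParticipantSummary:
    """Individual success classification from 12 run summaries.

    Maintenance: more than 50% successful runs (>= 7 of 12).  Improvement:
    OLS slope of the run means over run index, sign-matched to the group
    direction, and the last-vs-first session change (mean of runs 11-12
    minus mean of runs 1-2).  Variability improvement uses the per-run mean
    SDs, with decreasing variability (negative slope / negative change)
    counting as success in both groups.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(runs) != 12 and not allow_partial:
        raise ValueError("a full training has 12 runs (set allow_partial to override)")
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to classify")
    runs = sorted(runs, key=lambda r: r.run_index)
    n_succ = sum(r.successful for r in runs)
    means = np.array([r.run_mean_median for r in runs])
    sds = np.array([r.run_mean_sd for r in runs])
    idx = np.array([r.run_index for r in runs], dtype=float)

    slope = ols_slope(means, idx)
    sd_slope = ols_slope(sds, idx)
    lvf = float(means[-2:].mean() - means[:2].mean())
    sd_lvf = float(sds[-2:].mean() - sds[:2].mean())
    sign = 1.0 if direction == "up" else -1.0
    return ParticipantSummary(
        direction=direction,
        n_runs=len(runs),
        n_successful_runs=int(n_succ),
        classified_successful=bool(n_succ > len(runs) / 2),
        slope=slope,
        slope_successful=bool(sign * slope > 0),
        last_vs_first=lvf,
        last_vs_first_successful=bool(sign * lvf > 0),
        sd_slope=sd_slope,
        sd_slope_successful=bool(sd_slope < 0),
        sd_last_vs_first=sd_lvf,
        sd_last_vs_first_successful=bool(sd_lvf < 0),
    )


# ---------------------------------------------------------------------------
# Group-level tests
# ---------------------------------------------------------------------------

def cohen_d_one_sample(values) -> float:
    x = np.asarray(values, dtype=float)
    return float(np.mean(x) / np.std(x, ddof=1))


def group_maintenance_test(values) -> tuple[float, float, float]:
    """One-sample t-test of participant mean regulation against baseline 0.

    Returns (t, two-sided p, Cohen's d = mean/sd).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 participants")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance: t-test undefined")
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p), cohen_d_one_sample(x)


def group_change_test(first, last) -> tuple[float, float, float]:
    """Paired t-test of last-session vs first-session regulation.

    Differences are last - first; d = mean(diff)/sd(diff).
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(last, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = b - a
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0, 0.0
        raise ValueError("zero difference variance: t-test undefined")
    t, p = stats.ttest_rel(b, a)
    return float(t), float(p), cohen_d_one_sample(diff)


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test between independent groups, with
    Cohen's d on the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                     / (nx + ny - 2))
    d = float((x.mean() - y.mean()) / pooled) if pooled > 0 else 0.0
    return float(t), float(p), d


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_min_effect(n1: int, n2: int, alpha: float = 0.05,
                           power: float = 0.80, sides: int = 1) -> float:
    """Minimal detectable Cohen's d of an independent-samples t-test.

    Solved by bisection on d with noncentrality
    ``delta = d * sqrt(n1*n2/(n1+n2))`` and ``df = n1+n2-2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("power must exceed alpha")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    df = n1 + n2 - 2
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / sides, df)

    def achieved_power(d: float) -> float:
        delta = d * scale
        p = 1.0 - stats.nct.cdf(tcrit, df, delta)
        if sides == 2:
            p += stats.nct.cdf(-tcrit, df, delta)
        return p

    lo, hi = 1e-9, 0.1
    while achieved_power(hi) < power:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("failed to bracket the minimal effect")
    return float(optimize.brentq(lambda d: achieved_power(d) - power,
                                 lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def spearman_bonferroni(x, y, m: int = 1) -> tuple[float, float, float]:
    """Spearman rank correlation with Bonferroni adjustment over a family
    of ``m`` tests: returns (rho, p_raw, min(1, m*p_raw)).

    A constant input vector leaves the rank correlation undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), float(min(1.0, m * p))
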