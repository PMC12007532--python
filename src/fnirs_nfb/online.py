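"""Real-time feedback computation chain.

Emulates the full online processing of the closed loop, updated every
100 ms: device filtering (causal 0.01 Hz high-pass, 1 Hz low-pass, 5 s
moving average), per-trial CBSI motion correction with the noise-amplitude
ratio alpha and offsets estimated from the final 30 s of the preceding
no-regulation phase, normalization to the last 5 s baseline, 1 s linear
ramp smoothing of the displayed signal, mapping onto the 0-10 avatar
scale via 10*signal/(k*T) (sign-flipped for downregulation), reward
accrual at 0.01 EUR per second above level 5, and the between-run
adaptation of the scaling fraction k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import EventSchedule, HbRecording

SAMPLE_RATE = 10.0
EPS_SD = np.finfo(float).eps


# ---------------------------------------------------------------------------
# Device-equivalent filtering
# ---------------------------------------------------------------------------

def _device_sos(fs: float) -> tuple[np.ndarray, np.ndarray]:
    hp = sps.butter(2, 0.01, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
    return hp, lp


def device_filter_series(x: np.ndarray, fs: float = SAMPLE_RATE) -> np.ndarray:
    """Causal device chain on one series: HP 0.01 Hz, LP 1 Hz, 5 s moving
    average.  Causal filters reproduce what a streaming implementation
    computes sample by sample."""
    x = np.asarray(x, dtype=float)
    n_ma = int(round(5.0 * fs))
    if x.size < n_ma:
        raise ValueError("series shorter than the 5 s moving-average window")
    hp, lp = _device_sos(fs)
    # initialize each causal stage at steady state w.r.t. the first sample
    # so the filter startup transient does not leak into the first blocks
    y, _ = sps.sosfilt(hp, x, zi=sps.sosfilt_zi(hp) * x[0])
    y, _ = sps.sosfilt(lp, y, zi=sps.sosfilt_zi(lp) * y[0])
    b = np.ones(n_ma) / n_ma
    out, _ = sps.lfilter(b, [1.0], y, zi=sps.lfilter_zi(b, [1.0]) * y[0])
    return out


def device_frequency_response(freqs, fs: float = SAMPLE_RATE) -> np.ndarray:
    """Complex frequency response of the composite device chain."""
    freqs = np.asarray(freqs, dtype=float)
    hp, lp = _device_sos(fs)
    w = 2 * np.pi * freqs / fs
    _, h1 = sps.sosfreqz(hp, worN=w)
    _, h2 = sps.sosfreqz(lp, worN=w)
    n_ma = int(round(5.0 * fs))
    _, h3 = sps.freqz(np.ones(n_ma) / n_ma, [1.0], worN=w)
    return h1 * h2 * h3


def device_preprocess(raw: HbRecording) -> HbRecording:
    """Apply the device filter chain to every channel and chromophore."""
    hbo = np.empty_like(raw.hbo)
    hbr = np.empty_like(raw.hbr)
    for j in range(raw.n_channels):
        hbo[:, j] = device_filter_series(raw.hbo[:, j], raw.sample_rate)
        hbr[:, j] = device_filter_series(raw.hbr[:, j], raw.sample_rate)
    return raw.copy_with(hbo=hbo, hbr=hbr)


# ---------------------------------------------------------------------------
# CBSI and normalization
# ---------------------------------------------------------------------------

@dataclass
class CbsiParams:
    """Per-trial CBSI parameters from the pre-regulation window."""

    alpha: float
    hbo_offset: float
    hbr_offset: float
    degenerate: bool = False   # flat HbR window; alpha fell back to 1


def estimate_trial_params(pre_window_hbo, pre_window_hbr) -> CbsiParams:
    """Alpha (sd ratio) and offsets (means) from the no-regulation window.

    The window is the final 30 s of the no-regulation phase, or the whole
    phase when it is only 25 s long.  A flat HbR window makes the sd ratio
    undefined; alpha then falls back to 1 and the trial is flagged.
    """
    x = np.asarray(pre_window_hbo, dtype=float)
    y = np.asarray(pre_window_hbr, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pre windows must be equal-length 1-D arrays")
    sd_x = float(np.std(x, ddof=1))
    sd_y = float(np.std(y, ddof=1))
    degenerate = sd_y < EPS_SD
    alpha = 1.0 if degenerate else sd_x / sd_y
    return CbsiParams(alpha=alpha, hbo_offset=float(np.mean(x)),
                      hbr_offset=float(np.mean(y)), degenerate=degenerate)


def cbsi_correct(x, y, alpha: float):
    """Correlation-based signal improvement: (x - alpha*y) / 2.

    ``x``/``y`` are offset-corrected HbO/HbR values (scalars or arrays);
    alpha is the HbO/HbR noise-amplitude ratio.  Under perfect
    anticorrelation y = -x/alpha the correction returns x unchanged.
    """
    return (np.asarray(x, dtype=float) - alpha * np.asarray(y, dtype=float)) / 2.0


def normalize_feedback(x_corr, baseline_hbo,
                       md_interpretation: str = "median"):
    """Normalize the corrected signal to the last-5 s baseline window.

    Returns ``((x_corr - md(baseline)) / sd(baseline), degenerate)`` where
    ``md`` is the median (the default reading) or the mean.  A zero-sd
    baseline is guarded with machine epsilon and flagged.
    """
    base = np.asarray(baseline_hbo, dtype=float)
    if md_interpretation == "median":
        md = float(np.median(base))
    elif md_interpretation == "mean":
        md = float(np.mean(base))
    else:
        raise ValueError("md_interpretation must be 'median' or 'mean'")
    sd = float(np.std(base, ddof=1))
    degenerate = sd < EPS_SD
    if degenerate:
        sd = EPS_SD
    return (np.asarray(x_corr, dtype=float) - md) / sd, degenerate


def smooth_feedback(series) -> np.ndarray:
    """1 s linear-ramp smoothing of the displayed signal.

    Each time the target value changes, the displayed value ramps linearly
    from its current position to the new target over 1 s (10 display
    updates); an unchanged target lets the ramp complete, after which the
    display sits exactly on the target.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    n_ramp = int(round(1.0 * SAMPLE_RATE))
    out = np.empty_like(x)
    out[0] = x[0]
    start, target, step = x[0], x[0], n_ramp
    for i in range(1, x.size):
        if x[i] != target:
            start, target, step = out[i - 1], x[i], 0
        step += 1
        frac = min(1.0, step / n_ramp)
        out[i] = start + (target - start) * frac
    return out


# ---------------------------------------------------------------------------
# Mapping, reward, thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdState:
    """Individual threshold T and scaling fraction k of the display map."""

    T: float = 1.0
    k: float = 0.25
    reward_level: int = 5
    reward_rate: float = 0.01   # EUR per second above reward_level

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("threshold T must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")


def map_feedback(signal, state: ThresholdState, direction: str):
    """Map the feedback signal onto the 0-10 display scale.

    ``value = 10 * signal / (k*T)``, negated for the downregulation group,
    clamped to [0, 10].  The avatar image index is the value rounded half
    up (11 images, levels 0-10); the reward frame is on strictly above
    level ``reward_level``.
    Returns ``(feedback_value, image_index, reward_on)``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    raw = 10.0 * np.asarray(signal, dtype=float) / (state.k * state.T)
    if direction == "down":
        raw = -raw
    value = np.clip(raw, 0.0, 10.0)
    image = np.floor(value + 0.5).astype(int)
    reward_on = value > state.reward_level
    return value, image, reward_on


def accrue_reward(reward_on, state: ThresholdState | None = None,
                  sample_rate: float = SAMPLE_RATE) -> float:
    """Money earned in one trial: reward_rate x seconds with the frame on."""
    rate = (state or ThresholdState()).reward_rate
    seconds = float(np.count_nonzero(np.asarray(reward_on))) / sample_rate
    return rate * seconds


def initial_threshold(contrast_attention: float, contrast_vpt: float) -> float:
    """Individual threshold T from the two pre-assessment contrasts.

    T is the mean of the invalid-valid and PT-NPT activation contrasts;
    if the mean is negative, only the positive contrast is used; if both
    contrasts are negative, T defaults to 1.
    """
    if not (math.isfinite(contrast_attention) and math.isfinite(contrast_vpt)):
        raise ValueError("contrasts must be finite")
    if contrast_attention < 0 and contrast_vpt < 0:
        return 1.0
    t = (contrast_attention + contrast_vpt) / 2.0
    if t < 0:
        return max(contrast_attention, contrast_vpt)
    return t


@dataclass
class FeedbackTrace:
    """Feedback computation of one 30 s regulation trial."""

    run: int
    block: int
    t: np.ndarray = field(repr=False)
    feedback_signal: np.ndarray = field(repr=False)       # displayed (smoothed)
    feedback_signal_raw: np.ndarray = field(repr=False)   # before smoothing
    feedback_value: np.ndarray = field(repr=False)
    image_index: np.ndarray = field(repr=False)
    reward_on: np.ndarray = field(repr=False)
    earned: float = 0.0
    params: CbsiParams | None = None
    degenerate_baseline: bool = False


def adapt_k(trial_traces: list[FeedbackTrace],
            state: ThresholdState) -> ThresholdState:
    """Between-run difficulty adaptation.

    If the participant exceeded level 5 for at least 75% of the regulation
    time, pooled over the run's trials, k is incremented by 0.25 for the
    next run; otherwise it is unchanged.
    """
    pooled = np.concatenate([t.reward_on for t in trial_traces])
    if pooled.size == 0:
        raise ValueError("run has no regulation samples")
    if pooled.mean() >= 0.75:
        return replace(state, k=state.k + 0.25)
    return state


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

def run_closed_loop(recording: HbRecording, schedule: EventSchedule,
                    direction: str, state: ThresholdState | None = None,
                    md_interpretation: str = "median",
                    preprocessed: bool = False,
                    ) -> tuple[list[FeedbackTrace], ThresholdState, dict]:
    """Replay a recording through the full online chain.

    For every regulation trial: device-filtered stream -> per-trial alpha
    and offsets from the preceding no-regulation window -> per-sample CBSI
    -> baseline normalization (offset-corrected last-5 s HbO window) ->
    1 s ramp smoothing -> display mapping -> reward accrual; k adapts
    between runs.  Returns the traces, the final threshold state and a
    session log (k history, per-run earnings, degenerate-window flags).
    """
    state = state or ThresholdState()
    fs = recording.sample_rate
    need = int(round(schedule.total_duration * fs))
    if recording.n_samples < need - 1:
        raise ValueError(
            f"recording ({recording.n_samples} samples) does not span the "
            f"schedule ({need} samples)"
        )
    filt = recording if preprocessed else device_preprocess(recording)
    hbo_f, hbr_f = filt.channel_series(filt.feedback_channel)

    traces: list[FeedbackTrace] = []
    log = {
        "direction": direction,
        "initial_T": state.T,
        "initial_k": state.k,
        "k_per_run": [],
        "earned_per_run": [],
        "degenerate_trials": [],
    }
    blocks = schedule.blocks()
    for run, run_blocks in blocks.groupby("run"):
        run_traces = []
        for _, blk in run_blocks.iterrows():
            i_nr0 = int(round(blk["noreg_onset"] * fs))
            i_reg0 = int(round(blk["reg_onset"] * fs))
            i_reg1 = int(round((blk["reg_onset"] + blk["reg_duration"]) * fs))
            # alpha/offset window: last 30 s of no-regulation (whole phase
            # when only 25 s long)
            win = min(int(round(30.0 * fs)), i_reg0 - i_nr0)
            params = estimate_trial_params(
                hbo_f[i_reg0 - win:i_reg0], hbr_f[i_reg0 - win:i_reg0]
            )
            n_base = int(round(5.0 * fs))
            baseline = hbo_f[i_reg0 - n_base:i_reg0] - params.hbo_offset
            x = hbo_f[i_reg0:i_reg1] - params.hbo_offset
            y = hbr_f[i_reg0:i_reg1] - params.hbr_offset
            x_corr = cbsi_correct(x, y, params.alpha)
            sig_raw, degen = normalize_feedback(x_corr, baseline,
                                                md_interpretation)
            sig = smooth_feedback(sig_raw)
            value, image, reward_on = map_feedback(sig, state, direction)
            trace = FeedbackTrace(
                run=int(blk["run"]), block=int(blk["block"]),
                t=np.arange(i_reg0, i_reg1) / fs,
                feedback_signal=sig, feedback_signal_raw=sig_raw,
                feedback_value=value, image_index=image, reward_on=reward_on,
                earned=accrue_reward(reward_on, state, fs),
                params=params, degenerate_baseline=degen,
            )
            run_traces.append(trace)
            if params.degenerate or degen:
                log["degenerate_trials"].append(
                    {"run": int(blk["run"]), "block": int(blk["block"]),
                     "alpha_fallback": params.degenerate,
                     "flat_baseline": degen}
                )
        log["k_per_run"].append(state.k)
        log["earned_per_run"].append(sum(t.earned for t in run_traces))
        traces.extend(run_traces)
        state = adapt_k(run_traces, state)
    log["final_k"] = state.k
    log["total_earned"] = float(sum(t.earned for t in traces))
    return traces, state, log
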