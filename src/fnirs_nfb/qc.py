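"""Offline quality control and robustness re-analyses.

Bad channels are screened with coefficients of variation (CoV > 10% in
either chromophore, chromophore CoV difference > 5%) and a flat-line
detector (>= 1 s of identical samples).  Bad trials are replaced by the
average of the six neighboring trials; on-trial outliers beyond 3 SD are
replaced by the last retained observation.  Two robustness re-analyses
repeat the online computation with an extra step inserted before CBSI:
a stringent 0.01-0.09 Hz zero-phase bandpass (robust1), and a common
average reference over the 22 left-hemisphere channels (robust2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EventSchedule, HbRecording
from .online import ThresholdState, device_preprocess, run_closed_loop

COV_THRESHOLD = 10.0      # percent, per chromophore
COV_DIFF_THRESHOLD = 5.0  # percent, between chromophores
FLAT_SECONDS = 1.0
_EPS_MEAN = 1e-12


# ---------------------------------------------------------------------------
# Channel screening
# ---------------------------------------------------------------------------

def coefficient_of_variation(series) -> float:
    """CoV in percent: 100 * sd / |mean|.

    Computed on the device-exported concentration series including its mean
    level; a near-zero mean makes the ratio undefined and returns NaN (the
    channel is then routed to manual review rather than auto-excluded).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    m = abs(float(np.mean(x)))
    if m < _EPS_MEAN:
        return float("nan")
    return 100.0 * float(np.std(x, ddof=1)) / m


def has_flatline(series, sample_rate: float = 10.0,
                 flat_seconds: float = FLAT_SECONDS) -> bool:
    """True if the series contains >= flat_seconds of identical consecutive
    samples (>= 10 samples at 10 Hz; identity tolerance is exact, since
    device quantization makes exact repeats the meaningful signature)."""
    x = np.asarray(series, dtype=float)
    n_flat = int(round(flat_seconds * sample_rate))
    if x.size < n_flat:
        return False
    same = np.diff(x) == 0.0
    run = 0
    for s in same:
        run = run + 1 if s else 0
        if run + 1 >= n_flat:
            return True
    return False


@dataclass
class QcReport:
    """Channel-screening outcome plus an audit trail of overrides."""

    channels: pd.DataFrame = field(repr=False)
    audit: list = field(default_factory=list)
    trial_log: list = field(default_factory=list)

    def excluded_channels(self) -> list[str]:
        ch = self.channels
        return list(ch.loc[ch["excluded"] & ~ch["reincluded"], "channel"])

    def to_json(self, path=None) -> str:
        payload = {
            "channels": self.channels.to_dict(orient="records"),
            "audit": self.audit,
            "trial_log": self.trial_log,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def detect_bad_channels(recording: HbRecording,
                        cov_threshold: float = COV_THRESHOLD,
                        diff_threshold: float = COV_DIFF_THRESHOLD,
                        flat_seconds: float = FLAT_SECONDS) -> QcReport:
    """Screen every channel for excessive CoV, chromophore CoV mismatch,
    and flat lines; build the exclusion report."""
    rows = []
    for j, ch in enumerate(recording.channels):
        cov_o = coefficient_of_variation(recording.hbo[:, j])
        cov_r = coefficient_of_variation(recording.hbr[:, j])
        undefined = np.isnan(cov_o) or np.isnan(cov_r)
        diff = abs(cov_o - cov_r) if not undefined else float("nan")
        flat = (has_flatline(recording.hbo[:, j], recording.sample_rate, flat_seconds)
                or has_flatline(recording.hbr[:, j], recording.sample_rate, flat_seconds))
        reasons = []
        if not undefined:
            if cov_o > cov_threshold:
                reasons.append(f"cov_hbo {cov_o:.1f}% > {cov_threshold}%")
            if cov_r > cov_threshold:
                reasons.append(f"cov_hbr {cov_r:.1f}% > {cov_threshold}%")
            if diff > diff_threshold:
                reasons.append(f"cov difference {diff:.1f}% > {diff_threshold}%")
        if flat:
            reasons.append(f"flat line >= {flat_seconds} s")
        rows.append({
            "channel": ch,
            "cov_hbo": cov_o, "cov_hbr": cov_r, "cov_diff": diff,
            "cov_undefined": undefined,
            "flatline_found": flat,
            "excluded": bool(reasons),
            "reincluded": False,
            "reason": "; ".join(reasons) if reasons else
                      ("undefined CoV: manual review" if undefined else ""),
        })
    return QcReport(channels=pd.DataFrame(rows))


def reinclude_channel(report: QcReport, channel: str,
                      justification: str) -> QcReport:
    """Override an exclusion after visual inspection (audited; idempotent)."""
    if not justification or not justification.strip():
        raise ValueError("a non-empty justification is required")
    ch = report.channels
    idx = ch.index[ch["channel"] == channel]
    if len(idx) == 0:
        raise KeyError(f"unknown channel {channel!r}")
    i = idx[0]
    if not ch.at[i, "excluded"]:
        raise ValueError(f"channel {channel!r} is not excluded")
    if ch.at[i, "reincluded"]:
        return report
    ch.at[i, "reincluded"] = True
    report.audit.append({"channel": channel, "action": "reinclude",
                         "justification": justification})
    return report


# ---------------------------------------------------------------------------
# Trial repair
# ---------------------------------------------------------------------------

def interpolate_bad_trials(trials: list, index: int) -> np.ndarray:
    """Replace a bad trial by the sample-wise mean of its six neighboring
    trials (up to 3 before and 3 after, truncated at the sequence edges)."""
    if not 0 <= index < len(trials):
        raise IndexError("trial index out of range")
    neighbors = [np.asarray(trials[i], dtype=float)
                 for i in range(max(0, index - 3), min(len(trials), index + 4))
                 if i != index]
    if not neighbors:
        raise ValueError("no neighboring trials to interpolate from")
    return np.mean(neighbors, axis=0)


def remove_outlier_samples(trial_series) -> tuple[np.ndarray, int]:
    """Replace on-trial outliers (> 3 SD from the trial mean) by the last
    retained observation.

    Mean and SD are computed once on the original trial; consecutive
    outliers all receive the last retained pre-outlier value, and a leading
    outlier takes the first retained value.
    """
    x = np.asarray(trial_series, dtype=float)
    if x.size < 2:
        raise ValueError("trial must have at least 2 samples")
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return x.copy(), 0
    outlier = np.abs(x - m) > 3.0 * sd
    if not outlier.any():
        return x.copy(), 0
    out = x.copy()
    retained_idx = np.flatnonzero(~outlier)
    if retained_idx.size == 0:
        raise ValueError("all samples are outliers; trial must be interpolated")
    first_retained = x[retained_idx[0]]
    last = None
    for i in range(out.size):
        if outlier[i]:
            out[i] = first_retained if last is None else last
        else:
            last = x[i]
    return out, int(outlier.sum())


# ---------------------------------------------------------------------------
# Robustness transforms
# ---------------------------------------------------------------------------

def bandpass_series(x: np.ndarray, fs: float = 10.0,
                    low: float = 0.01, high: float = 0.09,
                    order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward)."""
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError("series too short for zero-phase bandpass filtering")
    return sps.sosfiltfilt(sos, x)


def bandpass_001_009(recording: HbRecording) -> HbRecording:
    """Stringent 0.01-0.09 Hz zero-phase bandpass per channel/chromophore,
    removing most systemic physiology (cardiac, respiration, Mayer waves)."""
    hbo = np.column_stack([
        bandpass_series(recording.hbo[:, j], recording.sample_rate)
        for j in range(recording.n_channels)
    ])
    hbr = np.column_stack([
        bandpass_series(recording.hbr[:, j], recording.sample_rate)
        for j in range(recording.n_channels)
    ])
    return recording.copy_with(hbo=hbo, hbr=hbr)


def common_average_reference(recording: HbRecording) -> HbRecording:
    """Subtract the mean left-hemisphere time series from the feedback
    channel (per chromophore); returns a single-channel recording."""
    left = recording.hemisphere_indices("left")
    if left.size == 0:
        raise ValueError("recording has no left-hemisphere channels")
    fb = recording.channel_index(recording.feedback_channel)
    if recording.hemispheres[fb] != "right":
        raise ValueError("feedback channel must be right-hemisphere for CAR")
    hbo = recording.hbo[:, fb] - recording.hbo[:, left].mean(axis=1)
    hbr = recording.hbr[:, fb] - recording.hbr[:, left].mean(axis=1)
    return HbRecording(
        sample_rate=recording.sample_rate,
        channels=[recording.feedback_channel], hemispheres=["right"],
        feedback_channel=recording.feedback_channel, hbo=hbo, hbr=hbr,
    )


# ---------------------------------------------------------------------------
# Offline re-analysis
# ---------------------------------------------------------------------------

VARIANTS = ("replication", "robust1", "robust2")


def offline_reanalysis(recording: HbRecording, schedule: EventSchedule,
                       direction: str, variant: str = "replication",
                       md_interpretation: str = "median") -> pd.DataFrame:
    """Recompute per-trial feedback-signal summaries offline.

    ``replication`` repeats the online chain exactly; ``robust1`` inserts
    the 0.01-0.09 Hz bandpass and ``robust2`` the common average reference,
    each applied after the device filter and before CBSI.  Returns one row
    per regulation trial with the median and SD of the feedback signal.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    filt = device_preprocess(recording)
    if variant == "robust1":
        fb = filt.channel_index(filt.feedback_channel)
        stream = HbRecording(
            sample_rate=filt.sample_rate,
            channels=[filt.feedback_channel], hemispheres=["right"],
            feedback_channel=filt.feedback_channel,
            hbo=bandpass_series(filt.hbo[:, fb], filt.sample_rate),
            hbr=bandpass_series(filt.hbr[:, fb], filt.sample_rate),
        )
    elif variant == "robust2":
        stream = common_average_reference(filt)
    else:
        fb = filt.channel_index(filt.feedback_channel)
        stream = HbRecording(
            sample_rate=filt.sample_rate,
            channels=[filt.feedback_channel], hemispheres=["right"],
            feedback_channel=filt.feedback_channel,
            hbo=filt.hbo[:, fb], hbr=filt.hbr[:, fb],
        )
    traces, _, _ = run_closed_loop(
        stream, schedule, direction, ThresholdState(),
        md_interpretation=md_interpretation, preprocessed=True,
    )
    rows = [{
        "run": tr.run, "block": tr.block,
        "trial_median": float(np.median(tr.feedback_signal)),
        "trial_sd": float(np.std(tr.feedback_signal, ddof=1)),
    } for tr in traces]
    return pd.DataFrame(rows)
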