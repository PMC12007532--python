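"""Synthetic fNIRS recordings and behavioral tables with known ground truth.

The generator emulates the study conditions of a single-channel rTPJ
neurofeedback training: a block-design hemodynamic response in the
designated feedback channel (scaled per run by a true regulation
amplitude), anticorrelated HbO/HbR, shared systemic physiology (cardiac,
respiration, Mayer waves), slow drift, white noise, and injectable
artifacts (motion spikes, flat lines, high-variance channels).  Behavioral
tables reproduce the Posner-cueing and visual perspective-taking (vPT)
designs with reaction times drawn from shifted-lognormal distributions
moment-matched to configurable cell means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import REGULATION, EventSchedule, HbRecording

# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

_PEAK_SHAPE = 7.0        # gamma shape -> mode at 6 s (scale 1)
_UNDER_SHAPE = 17.0      # undershoot mode at 16 s
_UNDER_RATIO = 6.0


def _double_gamma(t):
    return (stats.gamma.pdf(t, _PEAK_SHAPE)
            - stats.gamma.pdf(t, _UNDER_SHAPE) / _UNDER_RATIO)


_HRF_PEAK = float(np.max(_double_gamma(np.linspace(0.0, 30.0, 30001))))


def hrf(t):
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Peaks near 6 s with an undershoot near 16 s.  ``t`` is in seconds and
    must be non-negative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is defined for t >= 0 only")
    return _double_gamma(t) / _HRF_PEAK


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

PHYSIO_FREQS = {"cardiac": 1.1, "respiration": 0.3, "mayer": 0.1}

DEFAULT_PHYSIO_AMPLITUDES = {"cardiac": 0.2, "respiration": 0.3, "mayer": 0.5}


@dataclass
class ArtifactSpec:
    """One injected artifact: where, what, when, how big."""

    channel: str
    kind: str                 # spike | flatline | high_variance
    onset: float              # seconds
    duration: float           # seconds
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "flatline", "high_variance"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


@dataclass
class SimScenario:
    """Ground-truth parameters for one simulated participant's training.

    ``regulation_amplitudes`` holds the true hemodynamic response amplitude
    of the feedback channel for each scheduled run (signal units).  The up
    scenario defaults to a constant positive amplitude (activation that is
    sustained across training); the down scenario to a linear decline from
    positive to negative (initial stimulus-driven activation that
    disappears and reverses with training).
    """

    group_direction: str = "up"
    regulation_amplitudes: tuple[float, ...] = (0.5,) * 12
    physio_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_PHYSIO_AMPLITUDES))
    drift_slope: float = 0.02          # signal units per minute
    noise_sd: float = 0.05
    hbr_ratio: float = 0.5             # neural HbR = -hbr_ratio * neural HbO
    hbr_physio_scale: float = 0.3      # systemic share reaching HbR
    spike_hbr_scale: float = 0.5       # motion spikes co-occur in HbR
    dc_level: float = 0.0
    channels_per_hemisphere: int = 22
    feedback_channel: str = "R10"
    artifact_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_direction not in ("up", "down"):
            raise ValueError("group_direction must be 'up' or 'down'")
        if self.hbr_ratio <= 0:
            raise ValueError("hbr_ratio must be positive")


def default_scenario(direction: str, seed: int = 0, n_runs: int = 12,
                     channels_per_hemisphere: int = 22, **kwargs) -> SimScenario:
    """Study-condition scenario for one simulated participant."""
    if direction == "up":
        amps = tuple([0.5] * n_runs)
    elif direction == "down":
        amps = tuple(np.linspace(0.5, -0.25, n_runs))
    else:
        raise ValueError("direction must be 'up' or 'down'")
    fb = "R10" if channels_per_hemisphere >= 10 else "R01"
    return SimScenario(
        group_direction=direction,
        regulation_amplitudes=amps,
        channels_per_hemisphere=channels_per_hemisphere,
        feedback_channel=fb,
        seed=seed,
        **kwargs,
    )


def _channel_layout(n_per_hemi: int) -> tuple[list[str], list[str]]:
    channels = [f"L{i:02d}" for i in range(1, n_per_hemi + 1)]
    channels += [f"R{i:02d}" for i in range(1, n_per_hemi + 1)]
    hemis = ["left"] * n_per_hemi + ["right"] * n_per_hemi
    return channels, hemis


def simulate_recording(schedule: EventSchedule,
                       scenario: SimScenario) -> tuple[HbRecording, np.ndarray]:
    """Simulate an HbO/HbR recording spanning ``schedule``.

    Returns the recording and the clean neural ground-truth HbO per channel
    (same shape as ``recording.hbo``).  Only the feedback channel carries a
    neural response: the regulation boxcar of each run, scaled by that
    run's true amplitude, convolved with the canonical HRF (normalized so a
    long block plateaus at the run amplitude).  Systemic physiology, drift
    and white noise are superimposed; HbR mirrors the neural signal at
    ``-hbr_ratio`` with a scaled systemic share and independent noise.
    """
    if schedule.n_runs != len(scenario.regulation_amplitudes):
        raise ValueError(
            f"scenario has {len(scenario.regulation_amplitudes)} amplitudes "
            f"but schedule has {schedule.n_runs} runs"
        )
    fs = 10.0
    rng = np.random.default_rng(scenario.seed)
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs

    # regulation boxcar carrying per-run amplitudes
    boxcar = np.zeros(n)
    reg = schedule.events[schedule.events["condition"] == REGULATION]
    for _, row in reg.iterrows():
        amp = scenario.regulation_amplitudes[int(row["run"]) - 1]
        i0 = int(round(row["onset"] * fs))
        i1 = int(round((row["onset"] + row["duration"]) * fs))
        boxcar[i0:i1] = amp

    tk = np.arange(0, 32.0, 1.0 / fs)
    kernel = hrf(tk)
    # normalize so a sustained block plateaus at the boxcar amplitude
    resp = np.convolve(boxcar, kernel)[:n] / kernel.sum()

    channels, hemis = _channel_layout(scenario.channels_per_hemisphere)
    n_ch = len(channels)
    fb = channels.index(scenario.feedback_channel)

    neural = np.zeros((n, n_ch))
    neural[:, fb] = resp

    physio = np.zeros(n)
    for comp, freq in PHYSIO_FREQS.items():
        amp = scenario.physio_amplitudes.get(comp, 0.0)
        if amp:
            phase = rng.uniform(0, 2 * np.pi)
            physio += amp * np.sin(2 * np.pi * freq * t + phase)
    drift = scenario.drift_slope * t / 60.0

    shared = (scenario.dc_level + physio + drift)[:, None]
    hbo = neural + shared + rng.normal(0, scenario.noise_sd, (n, n_ch))
    hbr = (scenario.dc_level
           - scenario.hbr_ratio * neural
           + scenario.hbr_physio_scale * physio[:, None]
           + rng.normal(0, scenario.noise_sd, (n, n_ch)))

    for art in scenario.artifact_spec:
        art = art if isinstance(art, ArtifactSpec) else ArtifactSpec(*art)
        j = channels.index(art.channel)
        i0 = int(round(art.onset * fs))
        i1 = min(n, int(round((art.onset + art.duration) * fs)))
        if art.kind == "spike":
            hbo[i0:i1, j] += art.magnitude
            hbr[i0:i1, j] += art.magnitude * scenario.spike_hbr_scale
        elif art.kind == "flatline":
            hbo[i0:i1, j] = hbo[i0, j]
            hbr[i0:i1, j] = hbr[i0, j]
        else:  # high_variance
            hbo[i0:i1, j] += rng.normal(0, art.magnitude, i1 - i0)
            hbr[i0:i1, j] += rng.normal(0, art.magnitude, i1 - i0)

    rec = HbRecording(
        sample_rate=fs, channels=channels, hemispheres=hemis,
        feedback_channel=scenario.feedback_channel, hbo=hbo, hbr=hbr,
    )
    return rec, neural


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------

RT_SHIFT_MS = 150.0

# Default attention-task cells: pre from the baseline table, post derived by
# shifting each condition cell by the group's across-condition pre/post
# change (up -17 ms, down +15 ms) and rescaling SDs by the group's
# across-condition SD ratio.
_ATT_PRE = {
    ("up", "invalid"): (497.0, 69.0), ("up", "valid"): (452.0, 61.0),
    ("down", "invalid"): (508.0, 90.0), ("down", "valid"): (468.0, 94.0),
}
_ATT_DELTA = {"up": -17.0, "down": +15.0}
_ATT_SD_RATIO = {"up": 57.0 / 68.0, "down": 108.0 / 93.0}

_VPT_PRE = {
    ("up", "PT"): (3667.0, 327.0), ("up", "NPT"): (3611.0, 286.0),
    ("down", "PT"): (3630.0, 302.0), ("down", "NPT"): (3620.0, 272.0),
}
_VPT_DELTA = -130.0
_VPT_SD_RATIO = 295.0 / 270.0


def _default_cells() -> tuple[dict, dict]:
    means, sds = {}, {}
    for (g, cond), (m, s) in _ATT_PRE.items():
        means[(g, "pre", "attention", cond)] = m
        sds[(g, "pre", "attention", cond)] = s
        means[(g, "post", "attention", cond)] = m + _ATT_DELTA[g]
        sds[(g, "post", "attention", cond)] = s * _ATT_SD_RATIO[g]
    for (g, cond), (m, s) in _VPT_PRE.items():
        means[(g, "pre", "vpt", cond)] = m
        sds[(g, "pre", "vpt", cond)] = s
        means[(g, "post", "vpt", cond)] = m + _VPT_DELTA
        sds[(g, "post", "vpt", cond)] = s * _VPT_SD_RATIO
    return means, sds


def _default_accuracy() -> dict:
    acc = {}
    for time in ("pre", "post"):
        acc[("attention", "invalid", time)] = 0.98
        acc[("attention", "valid", time)] = 0.99
    acc[("vpt", "PT", "pre")] = 0.936
    acc[("vpt", "NPT", "pre")] = 0.976
    acc[("vpt", "PT", "post")] = 0.961
    acc[("vpt", "NPT", "post")] = 1.0
    return acc


@dataclass
class BehaviorSimConfig:
    """Cell means/SDs (ms) and accuracy rates driving the RT generator."""

    cell_means: dict = field(default_factory=lambda: _default_cells()[0])
    cell_sds: dict = field(default_factory=lambda: _default_cells()[1])
    accuracy_rates: dict = field(default_factory=_default_accuracy)
    n_invalid_blocks: int = 6     # 12 valid + 8 invalid trials each
    n_valid_blocks: int = 6       # 20 valid trials each
    n_vpt_blocks_per_condition: int = 6   # 4 trials per block
    rt_distribution: str = "shifted_lognormal"
    rt_shift_ms: float = RT_SHIFT_MS
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.accuracy_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"accuracy rate out of [0,1] for {k}")
        for k, v in self.cell_sds.items():
            if v <= 0:
                raise ValueError(f"non-positive SD for cell {k}")
        if self.rt_distribution != "shifted_lognormal":
            raise ValueError("only shifted_lognormal is implemented")


def shifted_lognormal_params(mean: float, sd: float,
                             shift: float = RT_SHIFT_MS) -> tuple[float, float]:
    """Moment-match (mu, sigma) of a lognormal so that shift + LN(mu, sigma)
    has the given mean and SD."""
    m = mean - shift
    if m <= 0:
        raise ValueError("cell mean must exceed the distribution shift")
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_rts(rng, config, group, time, task, condition, size):
    key = (group, time, task, condition)
    try:
        mean = config.cell_means[key]
        sd = config.cell_sds[key]
    except KeyError:
        raise KeyError(f"no RT cell configured for {key}") from None
    mu, sigma = shifted_lognormal_params(mean, sd, config.rt_shift_ms)
    return config.rt_shift_ms + rng.lognormal(mu, sigma, size)


def _draw_correct(rng, config, task, condition, time, size):
    key = (task, condition, time)
    try:
        rate = config.accuracy_rates[key]
    except KeyError:
        raise KeyError(f"no accuracy rate configured for {key}") from None
    return rng.random(size) < rate


def _vpt_block_order(rng, n_per_condition: int) -> list[str]:
    """Pseudo-random PT/NPT order, at most two consecutive same-condition."""
    labels = ["PT"] * n_per_condition + ["NPT"] * n_per_condition
    for _ in range(1000):
        order = list(rng.permutation(labels))
        ok = all(
            not (order[i] == order[i + 1] == order[i + 2])
            for i in range(len(order) - 2)
        )
        if ok:
            return order
    raise RuntimeError("could not satisfy block-order constraint")


def simulate_behavior(config: BehaviorSimConfig, group: str, time: str,
                      participant: str = "P01",
                      seed: int | None = None) -> pd.DataFrame:
    """Simulate one participant's trial table for one assessment.

    The attention task follows the blocked Posner design: 6 invalid blocks
    of 12 valid + 8 invalid trials and 6 valid blocks of 20 valid trials
    (240 trials, 192 valid / 48 invalid, i.e. 80%/20% cue validity), block
    order randomized.  The vPT (director) task has 4-trial PT and NPT
    blocks in pseudo-random order with at most two consecutive blocks of
    the same condition.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)

    block_types = (["invalid_block"] * config.n_invalid_blocks
                   + ["valid_block"] * config.n_valid_blocks)
    block_types = list(rng.permutation(block_types))
    task, block, btype_col, validity_col = [], [], [], []
    for b, btype in enumerate(block_types, start=1):
        if btype == "invalid_block":
            validities = list(rng.permutation(["valid"] * 12 + ["invalid"] * 8))
        else:
            validities = ["valid"] * 20
        task += ["attention"] * len(validities)
        block += [b] * len(validities)
        btype_col += [btype] * len(validities)
        validity_col += validities
    for b, cond in enumerate(_vpt_block_order(rng, config.n_vpt_blocks_per_condition),
                             start=1):
        task += ["vpt"] * 4
        block += [b] * 4
        btype_col += [cond] * 4
        validity_col += [cond] * 4

    task = np.array(task)
    condition = np.array(validity_col)
    rt = np.empty(task.size)
    correct = np.empty(task.size, dtype=bool)
    for tk in ("attention", "vpt"):
        for cond in np.unique(condition[task == tk]):
            sel = (task == tk) & (condition == cond)
            rt[sel] = _draw_rts(rng, config, group, time, tk, cond,
                                int(sel.sum()))
            correct[sel] = _draw_correct(rng, config, tk, cond, time,
                                         int(sel.sum()))
    return pd.DataFrame({
        "participant": participant, "group": group, "time": time,
        "task": task, "block": block, "block_type": btype_col,
        "trial_validity": np.where(task == "attention", condition, "n/a"),
        "condition": condition, "rt": rt, "correct": correct,
    })
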