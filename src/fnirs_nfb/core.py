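"""Core in-memory containers for the neurofeedback pipeline.

An :class:`HbRecording` holds a multi-channel two-chromophore (HbO/HbR)
concentration time series at a fixed sampling rate with one designated
feedback channel; an :class:`EventSchedule` holds the block design
(no-regulation / regulation / reward intervals grouped into runs and days).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")

#: Condition labels used throughout the event schedule.
NO_REGULATION = "no_regulation"
REGULATION = "regulation"
REWARD = "reward"


@dataclass
class HbRecording:
    """Multi-channel HbO/HbR concentration time series.

    Parameters
    ----------
    sample_rate
        Sampling rate in Hz (the acquisition device exports at 10 Hz).
    channels
        Ordered channel identifiers.
    hemispheres
        Hemisphere label (``"left"`` or ``"right"``) per channel, aligned
        with ``channels``.
    feedback_channel
        The single channel whose HbO activity drives the feedback display.
    hbo, hbr
        Arrays of shape ``(n_samples, n_channels)`` in device concentration
        units (mM·mm for a continuous-wave system).
    """

    sample_rate: float
    channels: list[str]
    hemispheres: list[str]
    feedback_channel: str
    hbo: np.ndarray
    hbr: np.ndarray

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.ndim == 1:
            self.hbo = self.hbo[:, None]
        if self.hbr.ndim == 1:
            self.hbr = self.hbr[:, None]
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shape")
        if self.hbo.shape[1] != len(self.channels):
            raise ValueError("channel count does not match data columns")
        if len(self.hemispheres) != len(self.channels):
            raise ValueError("hemispheres must be aligned with channels")
        bad = set(self.hemispheres) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")
        if self.feedback_channel not in self.channels:
            raise ValueError("feedback_channel not among channels")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds from recording start (0-based)."""
        return np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None

    def channel_series(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(hbo, hbr)`` series of one channel as 1-D views."""
        j = self.channel_index(channel)
        return self.hbo[:, j], self.hbr[:, j]

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        return np.array(
            [j for j, h in enumerate(self.hemispheres) if h == hemisphere],
            dtype=int,
        )

    def copy_with(self, hbo: np.ndarray | None = None,
                  hbr: np.ndarray | None = None) -> "HbRecording":
        return replace(
            self,
            channels=list(self.channels),
            hemispheres=list(self.hemispheres),
            hbo=self.hbo.copy() if hbo is None else hbo,
            hbr=self.hbr.copy() if hbr is None else hbr,
        )


@dataclass
class EventSchedule:
    """Ordered condition intervals of a neurofeedback training.

    ``events`` is a DataFrame with columns ``onset`` and ``duration``
    (seconds), ``condition`` (``no_regulation`` / ``regulation`` /
    ``reward``), ``run`` (1-based), ``block`` (1-based within run) and
    ``day``.  Intervals must be ordered and non-overlapping.
    """

    events: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("onset", "duration", "condition", "run", "block", "day")

    def __post_init__(self) -> None:
        ev = self.events
        missing = set(self.REQUIRED_COLUMNS) - set(ev.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        if (ev["duration"] <= 0).any():
            raise ValueError("all durations must be positive")
        onsets = ev["onset"].to_numpy(dtype=float)
        ends = onsets + ev["duration"].to_numpy(dtype=float)
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if np.any(onsets[1:] < ends[:-1] - 1e-9):
            raise ValueError("events overlap")
        self.events = ev.reset_index(drop=True)

    @property
    def n_runs(self) -> int:
        return int(self.events["run"].nunique())

    @property
    def total_duration(self) -> float:
        last = self.events.iloc[-1]
        return float(last["onset"] + last["duration"])

    def run_days(self) -> dict[int, int]:
        return dict(
            self.events.groupby("run")["day"].first().astype(int).items()
        )

    def blocks(self) -> pd.DataFrame:
        """One row per block: run, block, day and the three phase intervals.

        Columns: ``noreg_onset``, ``noreg_duration``, ``reg_onset``,
        ``reg_duration``, ``reward_onset``, ``reward_duration``.
        """
        rows = []
        for (run, block), grp in self.events.groupby(["run", "block"]):
            by_cond = {r["condition"]: r for _, r in grp.iterrows()}
            for cond in (NO_REGULATION, REGULATION, REWARD):
                if cond not in by_cond:
                    raise ValueError(
                        f"run {run} block {block} lacks a {cond} interval"
                    )
            rows.append({
                "run": int(run),
                "block": int(block),
                "day": int(grp["day"].iloc[0]),
                "noreg_onset": float(by_cond[NO_REGULATION]["onset"]),
                "noreg_duration": float(by_cond[NO_REGULATION]["duration"]),
                "reg_onset": float(by_cond[REGULATION]["onset"]),
                "reg_duration": float(by_cond[REGULATION]["duration"]),
                "reward_onset": float(by_cond[REWARD]["onset"]),
                "reward_duration": float(by_cond[REWARD]["duration"]),
            })
        return pd.DataFrame(rows).sort_values(["run", "block"]).reset_index(drop=True)

    def regulation_trials(self) -> pd.DataFrame:
        """One row per regulation trial: run, block, day, onset, duration."""
        b = self.blocks()
        return b[["run", "block", "day", "reg_onset", "reg_duration"]].rename(
            columns={"reg_onset": "onset", "reg_duration": "duration"}
        )
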