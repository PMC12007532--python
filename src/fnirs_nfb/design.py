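"""Training design: session configuration and event-schedule construction.

A full training comprises 12 neurofeedback runs spread over four days
(2, 4, 4, 2 runs).  Each run has six blocks; each block is a 25 s or 30 s
no-regulation phase, a 30 s regulation phase, and a 2 s reward display.
The no-regulation duration is jittered between 25 s and 30 s to avoid
locking the design to slow physiological rhythms (breathing, Mayer waves);
the jitter is balanced 3/3 within every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NO_REGULATION, REGULATION, REWARD, EventSchedule


@dataclass
class SessionConfig:
    """Parameters of a neurofeedback training session."""

    direction: str = "up"
    k0: float = 0.25
    reward_level: int = 5
    reward_rate: float = 0.01          # € per second above reward_level
    runs_per_day: tuple[int, ...] = (2, 4, 4, 2)
    blocks_per_run: int = 6
    regulation_s: float = 30.0
    no_regulation_s: tuple[float, float] = (25.0, 30.0)
    reward_display_s: float = 2.0
    sample_rate: float = 10.0
    md_interpretation: str = "median"  # online baseline central tendency
    jitter: str = "balanced"           # or "random"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.regulation_s <= 0 or self.reward_display_s <= 0:
            raise ValueError("durations must be positive")
        if any(d <= 0 for d in self.no_regulation_s):
            raise ValueError("durations must be positive")
        if self.md_interpretation not in ("median", "mean"):
            raise ValueError("md_interpretation must be 'median' or 'mean'")

    @property
    def n_runs(self) -> int:
        return int(sum(self.runs_per_day))

    @property
    def trials_per_training(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def regulation_minutes(self) -> float:
        """Total regulation time of a full training, in minutes."""
        return self.trials_per_training * self.regulation_s / 60.0


def build_schedule(config: SessionConfig | None = None,
                   seed: int = 0) -> EventSchedule:
    """Build the full training event schedule.

    The no-regulation durations are drawn pseudo-randomly from the two
    allowed values; with ``jitter="balanced"`` each run receives exactly
    three of each, permuted by ``seed``.  Runs are laid out back to back
    so onsets are absolute seconds from the start of the concatenated
    training record.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(seed)
    short, long = config.no_regulation_s
    day_of_run: list[int] = []
    for day, n in enumerate(config.runs_per_day, start=1):
        day_of_run.extend([day] * n)

    rows = []
    t = 0.0
    for run, day in enumerate(day_of_run, start=1):
        nb = config.blocks_per_run
        if config.jitter == "balanced":
            if nb % 2:
                raise ValueError("balanced jitter requires an even block count")
            durs = np.array([short] * (nb // 2) + [long] * (nb // 2))
            rng.shuffle(durs)
        else:
            durs = rng.choice([short, long], size=nb)
        for block, noreg in enumerate(durs, start=1):
            for cond, dur in (
                (NO_REGULATION, float(noreg)),
                (REGULATION, config.regulation_s),
                (REWARD, config.reward_display_s),
            ):
                rows.append({
                    "onset": t, "duration": dur, "condition": cond,
                    "run": run, "block": block, "day": day,
                })
                t += dur
    return EventSchedule(pd.DataFrame(rows))
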