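"""Transformed up-down adaptive staircases.

An n-down-1-up (transformed) staircase steps the stimulus toward "harder"
after ``n`` consecutive correct responses and toward "easier" after any
error, converging on the level where the probability of ``n`` consecutive
correct responses is 1/2, i.e. p(correct) = 0.5**(1/n).

Levels are maintained additively on the task's natural axis: dB contrast
for the detection and masking tasks (step 3 dB), log2 arc seconds for the
stereo task (a sqrt(2) multiplicative disparity step = +0.5 log2 units).
"Harder" means lower contrast for target-detection staircases, *higher*
mask contrast for the dichoptic-masking staircase (correct responses raise
the mask), and smaller disparity for stereo.

A staircase terminates at a fixed reversal count or trial cap, whichever
comes first.  Two staircases (one per eye, or per disparity sign) are run
randomly interleaved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StaircaseConfig",
    "Staircase",
    "StaircaseTerminatedError",
    "detection_config",
    "masking_config",
    "stereo_config",
    "convergence_probability",
    "run_staircase",
    "interleave",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Transformed up-down rule parameters.

    ``harder_sign`` is the signed direction of a "harder" step on the level
    axis: -1 for target detection (lower contrast) and stereo (smaller
    disparity), +1 for the masking task (higher mask contrast).
    """

    n_consecutive: int
    step: float
    harder_sign: int
    initial_level: float
    max_reversals: int = 9
    max_trials: int = 120
    level_min: float | None = None
    level_max: float | None = None

    def __post_init__(self) -> None:
        if self.n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.harder_sign not in (-1, 1):
            raise ValueError("harder_sign must be -1 or +1")
        if self.max_reversals < 1 or self.max_trials < 1:
            raise ValueError("termination bounds must be positive")


def detection_config(initial_level: float = -12.0) -> StaircaseConfig:
    """3-down-1-up, 3 dB steps, from -12 dB; contrast clamped at 0 dB."""
    return StaircaseConfig(
        n_consecutive=3, step=3.0, harder_sign=-1, initial_level=initial_level,
        max_reversals=9, max_trials=120, level_max=0.0,
    )


def masking_config(initial_level: float = -36.0) -> StaircaseConfig:
    """3-up-1-down on mask contrast (correct raises the mask), from -36 dB."""
    return StaircaseConfig(
        n_consecutive=3, step=3.0, harder_sign=+1, initial_level=initial_level,
        max_reversals=9, max_trials=120, level_max=0.0,
    )


def stereo_config(initial_arcsec: float = 512.0) -> StaircaseConfig:
    """2-down-1-up on log2 disparity, sqrt(2) steps, 30-trial cap; disparity
    clamped at 1 arc second (0 on the log2 axis)."""
    return StaircaseConfig(
        n_consecutive=2, step=0.5, harder_sign=-1,
        initial_level=math.log2(initial_arcsec),
        max_reversals=9, max_trials=30, level_min=0.0,
    )


def convergence_probability(n_consecutive: int) -> float:
    """Asymptotic percent-correct targeted by an n-down-1-up rule:
    0.5**(1/n) (0.794 for n=3, 0.707 for n=2, 0.5 for n=1)."""
    if n_consecutive < 1:
        raise ValueError("n_consecutive must be >= 1")
    return 0.5 ** (1.0 / n_consecutive)


class StaircaseTerminatedError(RuntimeError):
    pass


@dataclass
class Staircase:
    """Mutable staircase state driven by one response at a time."""

    config: StaircaseConfig
    level: float = field(init=False)
    consecutive_correct: int = field(init=False, default=0)
    last_direction: int | None = field(init=False, default=None)
    levels: list[float] = field(init=False, default_factory=list)
    outcomes: list[bool] = field(init=False, default_factory=list)
    reversal_levels: list[float] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        self.level = self.config.initial_level

    @property
    def n_trials(self) -> int:
        return len(self.levels)

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)

    @property
    def terminated(self) -> bool:
        return (
            self.n_reversals >= self.config.max_reversals
            or self.n_trials >= self.config.max_trials
        )

    def _clamp(self, level: float) -> float:
        cfg = self.config
        if cfg.level_min is not None:
            level = max(level, cfg.level_min)
        if cfg.level_max is not None:
            level = min(level, cfg.level_max)
        return level

    def update(self, correct: bool) -> None:
        """Record one trial at the current level and apply the rule."""
        if self.terminated:
            raise StaircaseTerminatedError("update on a terminated staircase")
        cfg = self.config
        self.levels.append(self.level)
        self.outcomes.append(bool(correct))
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= cfg.n_consecutive:
                self._step(cfg.harder_sign)
        else:
            self._step(-cfg.harder_sign)

    def _step(self, direction: int) -> None:
        if self.last_direction is not None and direction != self.last_direction:
            # the reversal happens at the level just responded to
            self.reversal_levels.append(self.levels[-1])
        self.last_direction = direction
        self.level = self._clamp(self.level + direction * self.config.step)
        self.consecutive_correct = 0


def run_staircase(
    config: StaircaseConfig,
    respond: Callable[[float], bool],
) -> Staircase:
    """Run one staircase to termination against a response callback."""
    sc = Staircase(config)
    while not sc.terminated:
        sc.update(respond(sc.level))
    return sc


def interleave(
    staircases: Sequence[Staircase],
    respond_fns: Sequence[Callable[[float], bool]],
    rng: np.random.Generator,
) -> list[int]:
    """Run several staircases randomly interleaved until all terminate.

    Each trial is drawn from a uniformly random non-terminated member.
    Returns the schedule (index of the staircase serving each trial).
    """
    if len(staircases) != len(respond_fns):
        raise ValueError("need one response callback per staircase")
    schedule: list[int] = []
    while True:
        active = [i for i, s in enumerate(staircases) if not s.terminated]
        if not active:
            return schedule
        i = int(rng.choice(active))
        staircases[i].update(respond_fns[i](staircases[i].level))
        schedule.append(i)
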