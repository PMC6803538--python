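"""Experimental paradigm: stimulus geometry and the trial schedule.

The paradigm is a three-condition action-observation task.  On each trial a
hand-cup interaction is shown under one of three intentions — grasp to drink
(Sd), grasp to move (Sm), or an unclear touch (Su) — with the cup drawn in
one of seven colors, each condition x color cell repeated a fixed number of
times.  Trials run pre-rest, cue, observation, post-rest and are split into
equal sessions separated by long rests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("Sd", "Sm", "Su")


class ConfigurationError(ValueError):
    """Raised for invalid paradigm or pipeline configuration."""


class GeometryError(ValueError):
    """Raised for invalid stimulus geometry."""


def visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``.

    Uses the full-angle formula 2*arctan(extent / (2*distance)).
    """
    if distance_cm <= 0:
        raise GeometryError(f"viewing distance must be positive, got {distance_cm}")
    if extent_cm < 0:
        raise GeometryError(f"extent must be non-negative, got {extent_cm}")
    return math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))


@dataclass(frozen=True)
class StimulusGeometry:
    """Physical size of the stimulus and viewing distance (cm)."""

    width_cm: float = 28.0
    height_cm: float = 16.0
    viewing_distance_cm: float = 80.0

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def horizontal_angle_deg(self) -> float:
        return visual_angle(self.width_cm, self.viewing_distance_cm)

    @property
    def vertical_angle_deg(self) -> float:
        return visual_angle(self.height_cm, self.viewing_distance_cm)


@dataclass(frozen=True)
class ParadigmConfig:
    """Counts and timing of the action-observation paradigm.

    Defaults give 3 conditions x 7 colors x 4 repetitions = 84 trials in 4
    sessions of 21, each trial 6 + 0.5 + 3.5 + 6 = 16 s, with 120 s between
    sessions (28.4 min total).
    """

    n_conditions: int = 3
    n_colors: int = 7
    n_reps: int = 4
    pre_rest_s: float = 6.0
    cue_s: float = 0.5
    observation_s: float = 3.5
    post_rest_s: float = 6.0
    n_sessions: int = 4
    inter_session_rest_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pre_rest_s", "cue_s", "observation_s", "post_rest_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.inter_session_rest_s < 0:
            raise ConfigurationError("inter_session_rest_s must be non-negative")
        for name in ("n_conditions", "n_colors", "n_reps", "n_sessions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_trials % self.n_sessions != 0:
            raise ConfigurationError(
                f"{self.n_trials} trials cannot be split into "
                f"{self.n_sessions} equal sessions"
            )

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.n_colors * self.n_reps

    @property
    def trial_duration_s(self) -> float:
        return self.pre_rest_s + self.cue_s + self.observation_s + self.post_rest_s

    @property
    def condition_names(self) -> tuple[str, ...]:
        if self.n_conditions == len(CONDITIONS):
            return CONDITIONS
        return tuple(f"S{i + 1}" for i in range(self.n_conditions))


@dataclass(frozen=True)
class Trial:
    index: int
    condition: str
    color: int
    session: int
    observation_onset_s: float


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial records for one run plus the total run duration."""

    trials: tuple[Trial, ...]
    total_duration_s: float
    config: ParadigmConfig = field(default_factory=ParadigmConfig)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([t.observation_onset_s for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "color": [t.color for t in self.trials],
                "session": [t.session for t in self.trials],
                "observation_onset_s": [t.observation_onset_s for t in self.trials],
            }
        )


def build_schedule(config: ParadigmConfig | None = None) -> TrialSchedule:
    """Randomize the full condition x color x repetition crossing into sessions.

    The permutation is drawn from ``config.seed``; trial onsets are laid out
    back-to-back within sessions with the configured inter-session rest.
    """
    config = config or ParadigmConfig()
    rng = np.random.default_rng(config.seed)
    cells = [
        (cond, color)
        for cond in config.condition_names
        for color in range(1, config.n_colors + 1)
        for _ in range(config.n_reps)
    ]
    order = rng.permutation(len(cells))
    per_session = config.n_trials // config.n_sessions
    trial_dur = config.trial_duration_s

    trials: list[Trial] = []
    for i, cell_idx in enumerate(order):
        cond, color = cells[cell_idx]
        session = i // per_session
        trial_start = (
            session * (per_session * trial_dur + config.inter_session_rest_s)
            + (i % per_session) * trial_dur
        )
        onset = trial_start + config.pre_rest_s + config.cue_s
        trials.append(Trial(i, cond, color, session + 1, onset))

    total = (
        config.n_trials * trial_dur
        + (config.n_sessions - 1) * config.inter_session_rest_s
    )
    return TrialSchedule(tuple(trials), total, config)
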