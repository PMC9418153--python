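"""Mental-arithmetic-task (MAT) timeline.

The MAT is a three-stage stress protocol: an eyes-closed rest stage, a
task stage made of repeated arithmetic cycles (question, countdown,
answer, feedback), and an eyes-closed recovery stage.  With the default
settings (60 s rest, 45 cycles of 1+4+1+1 = 7 s, 180 s recovery) the
whole run lasts 555 s.
"""

from __future__ import annotations

from dataclasses import dataclass


class ProtocolError(ValueError):
    """Raised for invalid MAT timeline settings."""


@dataclass(frozen=True)
class MATProtocol:
    """Three-stage MAT timeline, all durations in seconds.

    A cycle is one question/countdown/answer/feedback sequence; the task
    stage is ``n_cycles`` back-to-back cycles.
    """

    rest_duration: float = 60.0
    question_duration: float = 1.0
    countdown_duration: float = 4.0
    answer_duration: float = 1.0
    feedback_duration: float = 1.0
    n_cycles: int = 45
    recovery_duration: float = 180.0

    def __post_init__(self) -> None:
        durations = (
            self.rest_duration,
            self.question_duration,
            self.countdown_duration,
            self.answer_duration,
            self.feedback_duration,
            self.recovery_duration,
        )
        if any(d <= 0 for d in durations):
            raise ProtocolError("all MAT durations must be positive")
        if self.n_cycles < 1:
            raise ProtocolError("n_cycles must be >= 1")

    @property
    def cycle_duration(self) -> float:
        return (
            self.question_duration
            + self.countdown_duration
            + self.answer_duration
            + self.feedback_duration
        )

    @property
    def task_duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.task_duration + self.recovery_duration

    def stage_boundaries(self) -> dict[str, tuple[float, float]]:
        """Half-open stage spans in seconds: rest, task, recovery."""
        r = self.rest_duration
        t = r + self.task_duration
        return {
            "rest": (0.0, r),
            "task": (r, t),
            "recovery": (t, self.total_duration),
        }

    def cycle_onsets(self) -> list[float]:
        """Onset time (s) of each arithmetic cycle within the task stage."""
        return [
            self.rest_duration + i * self.cycle_duration
            for i in range(self.n_cycles)
        ]


def build_protocol(**overrides: float | int) -> MATProtocol:
    """Construct a MAT timeline, optionally overriding any duration.

    Accepts the ``MATProtocol`` field names as keyword arguments.  With
    no overrides, the default 555 s protocol is returned.
    """
    valid = set(MATProtocol.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ProtocolError(f"unknown protocol settings: {sorted(unknown)}")
    return MATProtocol(**overrides)  # type: ignore[arg-type]
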