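"""Block design of the imagined-walking session.

Two 60 s task blocks — motor imagery alone (``MI``) and motor imagery with
rhythmic auditory stimulation (``MI+RAS``) — each made of three contiguous
20 s trials, separated and flanked by 30 s rest periods.  All boundaries
fall on sample ticks at the 20 Hz acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Event:
    onset: float       # s from session start
    duration: float    # s
    condition: str


@dataclass(frozen=True)
class TaskDesign:
    """Timing of a two-condition block-design session.

    Parameters
    ----------
    sampling_rate : float
        Acquisition rate in Hz (default 20).
    conditions : tuple of str
        Ordered condition labels.
    task_duration : float
        Length of one task block in seconds (default 60 = 3 x 20 s trials).
    n_trials : int
        Trials per block; trials are contiguous (the stimulus video repeats
        back to back).
    rest_duration : float
        Rest before, between and after blocks, in seconds.
    """

    sampling_rate: float = 20.0
    conditions: tuple[str, ...] = ("MI", "MI+RAS")
    task_duration: float = 60.0
    n_trials: int = 3
    rest_duration: float = 30.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.conditions:
            raise ValueError("design needs at least one condition")
        if self.task_duration <= 0 or self.rest_duration < 0:
            raise ValueError("durations must be positive")
        trial = self.task_duration / self.n_trials
        for t in (self.task_duration, self.rest_duration, trial):
            ticks = t * self.sampling_rate
            if abs(ticks - round(ticks)) > 1e-9:
                raise ValueError(f"duration {t} s does not fall on a sample tick")

    @property
    def trial_duration(self) -> float:
        return self.task_duration / self.n_trials

    @property
    def total_duration(self) -> float:
        k = len(self.conditions)
        return k * self.task_duration + (k + 1) * self.rest_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    def block_onset(self, condition: str) -> float:
        i = self.conditions.index(condition)
        return self.rest_duration + i * (self.task_duration + self.rest_duration)

    def block_events(self) -> list[Event]:
        """One event per condition block (onset, 60 s, label)."""
        return [Event(self.block_onset(c), self.task_duration, c) for c in self.conditions]

    def trial_events(self) -> list[Event]:
        """One event per 20 s trial, three contiguous trials per block."""
        out: list[Event] = []
        for c in self.conditions:
            t0 = self.block_onset(c)
            for j in range(self.n_trials):
                out.append(Event(t0 + j * self.trial_duration, self.trial_duration, c))
        return out


DEFAULT_DESIGN = TaskDesign()
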