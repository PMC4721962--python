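"""Block-design stimulation protocols.

A run consists of ``n_cycles`` repetitions of a fixed-length cycle, each
beginning with a pulse train (light on) followed by a rest period, optionally
preceded by a baseline rest block.  Pulse timing is fully determined by the
stimulation frequency and the duty cycle — the fraction of each pulse period
during which light is delivered — so that total light delivery is constant
across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["StimulusProtocol", "make_protocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of a block-design optogenetic stimulation run.

    Parameters
    ----------
    frequency_hz : float
        Pulse repetition rate during the train (e.g. 10, 40 or 100 Hz).
    duty_fraction : float
        Fraction of each pulse period during which light is on, in (0, 1].
        A 30% duty cycle at 10 Hz gives 30 ms pulses.
    train_duration_s : float
        Duration of the pulse train at the start of each cycle.
    cycle_period_s : float
        Full cycle length (train + rest).
    n_cycles : int
        Number of stimulation cycles per run.
    baseline_s : float
        Rest period preceding the first cycle (used as the percent-modulation
        reference in the imaging analysis).
    """

    frequency_hz: float
    duty_fraction: float = 0.30
    train_duration_s: float = 20.0
    cycle_period_s: float = 60.0
    n_cycles: int = 6
    baseline_s: float = 30.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency_hz must be positive, got {self.frequency_hz}")
        if not 0.0 < self.duty_fraction <= 1.0:
            raise ValueError(f"duty_fraction must be in (0, 1], got {self.duty_fraction}")
        if self.train_duration_s > self.cycle_period_s:
            raise ValueError(
                f"train ({self.train_duration_s} s) does not fit inside the "
                f"cycle ({self.cycle_period_s} s)"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.baseline_s < 0:
            raise ValueError("baseline_s must be >= 0")
        n_pulses = self.frequency_hz * self.train_duration_s
        if abs(n_pulses - round(n_pulses)) > 1e-9:
            raise ValueError(
                f"frequency_hz × train_duration_s = {n_pulses} is not an integer "
                "number of pulses per train"
            )

    @property
    def pulse_period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def pulse_width_ms(self) -> float:
        """On-time of a single pulse in milliseconds."""
        return self.duty_fraction / self.frequency_hz * 1000.0

    @property
    def n_pulses_per_train(self) -> int:
        return int(round(self.frequency_hz * self.train_duration_s))

    @property
    def run_duration_s(self) -> float:
        """Total run length including the leading baseline."""
        return self.baseline_s + self.n_cycles * self.cycle_period_s

    def train_onsets_s(self, include_baseline: bool = True) -> np.ndarray:
        """Onset times of each pulse train relative to run start."""
        offset = self.baseline_s if include_baseline else 0.0
        return offset + np.arange(self.n_cycles) * self.cycle_period_s

    def pulse_onsets_s(self, cycle: int | None = None, include_baseline: bool = True) -> np.ndarray:
        """Onset times of individual light pulses.

        With ``cycle=None`` onsets for all cycles are returned, relative to
        run start; with a cycle index, onsets for that cycle only.
        """
        within = np.arange(self.n_pulses_per_train) * self.pulse_period_s
        trains = self.train_onsets_s(include_baseline)
        if cycle is not None:
            return trains[cycle] + within
        return (trains[:, None] + within[None, :]).ravel()

    def boxcar(self, tr_s: float, include_baseline: bool = True) -> np.ndarray:
        """Stimulation indicator sampled on the imaging frame grid (1 = train on)."""
        n = int(round((self.run_duration_s if include_baseline else self.n_cycles * self.cycle_period_s) / tr_s))
        t = np.arange(n) * tr_s
        onsets = self.train_onsets_s(include_baseline)
        box = np.zeros(n)
        for t0 in onsets:
            box[(t >= t0) & (t < t0 + self.train_duration_s)] = 1.0
        return box

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


def make_protocol(
    frequency_hz: float,
    duty_fraction: float = 0.30,
    train_duration_s: float = 20.0,
    cycle_period_s: float = 60.0,
    n_cycles: int = 6,
    baseline_s: float = 30.0,
) -> StimulusProtocol:
    """Construct a validated :class:`StimulusProtocol`."""
    return StimulusProtocol(
        frequency_hz=frequency_hz,
        duty_fraction=duty_fraction,
        train_duration_s=train_duration_s,
        cycle_period_s=cycle_period_s,
        n_cycles=n_cycles,
        baseline_s=baseline_s,
    )
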