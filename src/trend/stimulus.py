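"""Block-design stimulus functions driving the DCM generators.

A :class:`StimulusDesign` holds one or more input channels, each a train of
boxcar events.  Driving channels inject activity into regions through the C
matrix; modulatory channels scale connections bilinearly through the B
matrices.  Events follow the half-open convention ``[onset, onset+duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusDesign", "evaluate_stimulus", "default_block_design"]


@dataclass
class StimulusDesign:
    """Boxcar input channels on a fine simulation grid.

    Parameters
    ----------
    n_channels : int
        Total number of input channels.
    channel_role : list of str
        ``"driving"`` or ``"modulatory"`` per channel.
    events : list of list of (onset, duration, amplitude)
        Event train per channel, in seconds / arbitrary units.
    total_duration : float
        Length of the run in seconds.
    dt_sim : float
        Integration step in seconds; must not exceed the sampling TR.
    """

    n_channels: int
    channel_role: list
    events: list
    total_duration: float
    dt_sim: float = 0.01

    def __post_init__(self):
        if self.n_channels != len(self.channel_role) or self.n_channels != len(self.events):
            raise ValueError("channel_role and events must have n_channels entries")
        for role in self.channel_role:
            if role not in ("driving", "modulatory"):
                raise ValueError(f"unknown channel role {role!r}")
        if not self.dt_sim > 0:
            raise ValueError("dt_sim must be positive")
        if not self.total_duration > 0:
            raise ValueError("total_duration must be positive")
        for ch in self.events:
            for onset, duration, _amp in ch:
                if onset < 0:
                    raise ValueError("event onsets must be >= 0")
                if duration <= 0:
                    raise ValueError("event durations must be > 0")
                if onset + duration > self.total_duration + 1e-9:
                    raise ValueError("event extends past total_duration")

    @property
    def driving_channels(self) -> list:
        return [i for i, r in enumerate(self.channel_role) if r == "driving"]

    @property
    def modulatory_channels(self) -> list:
        return [i for i, r in enumerate(self.channel_role) if r == "modulatory"]

    @property
    def n_driving(self) -> int:
        return len(self.driving_channels)

    @property
    def n_modulatory(self) -> int:
        return len(self.modulatory_channels)

    def on_grid(self, dt: float | None = None) -> np.ndarray:
        """Evaluate all channels on the regular grid t = 0, dt, 2dt, ...

        Returns an array of shape ``(n_steps, n_channels)`` where
        ``n_steps = round(total_duration / dt)``.
        """
        dt = self.dt_sim if dt is None else dt
        n_steps = int(round(self.total_duration / dt))
        t = np.arange(n_steps) * dt
        U = np.zeros((n_steps, self.n_channels))
        for m, ch in enumerate(self.events):
            for onset, duration, amp in ch:
                # half-open [onset, onset+duration)
                sel = (t >= onset - 1e-12) & (t < onset + duration - 1e-12)
                U[sel, m] = amp
        return U

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "channel_role": list(self.channel_role),
            "events": [[list(map(float, e)) for e in ch] for ch in self.events],
            "total_duration": float(self.total_duration),
            "dt_sim": float(self.dt_sim),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusDesign":
        return cls(
            n_channels=int(d["n_channels"]),
            channel_role=list(d["channel_role"]),
            events=[[tuple(e) for e in ch] for ch in d["events"]],
            total_duration=float(d["total_duration"]),
            dt_sim=float(d.get("dt_sim", 0.01)),
        )


def evaluate_stimulus(design: StimulusDesign, t: float) -> np.ndarray:
    """Channel amplitudes at time ``t`` (half-open boxcar convention)."""
    if t < 0 or t > design.total_duration:
        raise ValueError(f"t={t} outside [0, {design.total_duration}]")
    u = np.zeros(design.n_channels)
    for m, ch in enumerate(design.events):
        for onset, duration, amp in ch:
            if onset <= t < onset + duration:
                u[m] = amp
    return u


def default_block_design(
    n_driving: int = 2,
    total_duration: float = 400.0,
    on: float = 20.0,
    off: float = 40.0,
    amplitude: float = 1.0,
    dt_sim: float = 0.01,
) -> StimulusDesign:
    """Benchmark block design: alternating ON/OFF boxcars, channels staggered.

    Channel ``m`` starts its first block at ``on + m*(on+off)/n_driving`` so the
    driving inputs interleave rather than coincide.
    """
    period = on + off
    events = []
    for m in range(n_driving):
        offset = on + m * period / max(n_driving, 1)
        ch = []
        t0 = offset
        while t0 + on <= total_duration:
            ch.append((t0, on, amplitude))
            t0 += period
        events.append(ch)
    return StimulusDesign(
        n_channels=n_driving,
        channel_role=["driving"] * n_driving,
        events=events,
        total_duration=total_duration,
        dt_sim=dt_sim,
    )
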