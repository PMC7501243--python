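"""Experiment protocol timelines.

A timeline is the piecewise schedule of an experiment: for each phase
the flow rate, the cumulative magnet turns at the phase boundaries
(linear in between), and the camera frame rate.  Both the simulator and
the classification pipeline consult the same timeline, so phase names
are a closed vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

PHASE_NAMES = {
    "reversal", "coil_neg", "uncoil", "coil_pos", "force_window",
    "partial_uncoil", "reaction", "treadmill", "sds_wash",
}


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class Phase:
    name: str
    t0: float            # s
    t1: float            # s
    flow: float          # ul/min
    turns_start: float   # cumulative magnet turns at t0
    turns_end: float     # cumulative magnet turns at t1
    frame_rate: float    # Hz

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ProtocolError(f"unknown phase name {self.name!r}")
        if self.t1 <= self.t0:
            raise ProtocolError(f"phase {self.name}: t1 must exceed t0")
        if self.frame_rate <= 0:
            raise ProtocolError(f"phase {self.name}: frame rate must be positive")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def turns_at(self, t: float) -> float:
        frac = (t - self.t0) / (self.t1 - self.t0)
        return self.turns_start + frac * (self.turns_end - self.turns_start)


@dataclass
class ProtocolTimeline:
    phases: list[Phase] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(b.t0 - a.t1) > 1e-9:
                raise ProtocolError(
                    f"phases {a.name} and {b.name} are not contiguous"
                )

    @property
    def t_start(self) -> float:
        return self.phases[0].t0

    @property
    def t_end(self) -> float:
        return self.phases[-1].t1

    def phase(self, name: str) -> Phase:
        for ph in self.phases:
            if ph.name == name:
                return ph
        raise ProtocolError(f"timeline has no {name!r} phase")

    def has_phase(self, name: str) -> bool:
        return any(ph.name == name for ph in self.phases)

    def phase_at(self, t: float) -> Phase:
        for ph in self.phases:
            if ph.t0 <= t <= ph.t1:
                return ph
        raise ProtocolError(f"time {t} outside the timeline")

    def turns_at(self, t: float) -> float:
        return self.phase_at(t).turns_at(t)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {"phases": [vars(ph) | {} for ph in self.phases]}

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolTimeline":
        return cls(phases=[Phase(**p) for p in d["phases"]])

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ProtocolTimeline":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_timeline(
    reaction_duration: float = 300.0,
    flow_low: float = 2.5,
    flow_high: float = 40.0,
    coil_turns: float = 150.0,
    remaining_pos_turns: float = 40.0,
    turn_rate: float = 2.0,
    frame_rate: float = 4.0,
    force_frame_rate: float = 33.0,
    force_window_s: float = 120.0,
) -> ProtocolTimeline:
    """The standard classification protocol.

    Flow reversal (mobility/attachment), a +/- coiling series at high
    flow (coilability and tether multiplicity), a high-frame-rate force
    window at the reaction flow, a partial uncoil at the reaction flow
    that leaves the tether positively supercoiled (and calibrates the
    nm-per-turn slope), then the enzyme reaction phase.
    """
    coil_s = coil_turns / turn_rate
    uncoil_partial_s = (coil_turns - remaining_pos_turns) / turn_rate
    t = 0.0
    phases = []

    def add(name, dur, flow, n0, n1, fr):
        nonlocal t
        phases.append(Phase(name, t, t + dur, flow, n0, n1, fr))
        t += dur

    add("reversal", 60.0, flow_low, 0.0, 0.0, frame_rate)
    add("coil_neg", coil_s, flow_high, 0.0, -coil_turns, frame_rate)
    add("uncoil", coil_s, flow_high, -coil_turns, 0.0, frame_rate)
    add("force_window", force_window_s, flow_low, 0.0, 0.0, force_frame_rate)
    add("coil_pos", coil_s, flow_high, 0.0, coil_turns, frame_rate)
    add("partial_uncoil", uncoil_partial_s, flow_low, coil_turns, remaining_pos_turns, frame_rate)
    add("reaction", reaction_duration, flow_low, remaining_pos_turns, remaining_pos_turns, frame_rate)
    return ProtocolTimeline(phases=phases)
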