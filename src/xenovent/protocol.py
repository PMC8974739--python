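"""Gas-delivery protocols and the CT frame clock.

A ventilation experiment is a piecewise-constant schedule of supply gas
(room air or 100% xenon) and flow regime (laminar, or laminar superimposed
with a 45 Hz / 25 mbar pressure pulsation) delivered to the input nostril,
while the scanner acquires one dual-energy volume every ``frame_interval_s``
seconds.  Two published schedules are built in:

``pre_fess``
    69 s, five phases: room air (0-10.5 s), laminar xenon (10.5-34.5 s),
    pulsating xenon (34.5-52.5 s), laminar room-air washout (52.5-63 s),
    pulsating room-air washout (63-69 s).  46 frames at 1.5 s.

``post_fess``
    49.5 s, three phases: room air, laminar xenon, pulsating xenon.
    33 frames at 1.5 s; washout was not acquired.

Phase intervals are half-open ``[start_s, end_s)``: an event time belongs to
the phase it starts.  Frame timestamps mark the start of each acquisition
interval, so frame k is at ``k * frame_interval_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping

import numpy as np

from .errors import TimeOutOfRangeError, UnknownVariantError

__all__ = [
    "Gas",
    "Flow",
    "Phase",
    "Protocol",
    "build_protocol",
    "frame_times",
    "phase_at",
    "PROTOCOL_VARIANTS",
]


class Gas(str, Enum):
    AIR = "air"
    XENON = "xenon"


class Flow(str, Enum):
    LAMINAR = "laminar"
    PULSATING = "pulsating"


def _default_metadata() -> dict[str, Any]:
    # Descriptive constants of the delivery hardware; the kinetics model
    # depends only on the flow enum, never on these numbers.
    return {
        "pulsation_frequency_hz": 45.0,
        "pulsation_amplitude_mbar": 25.0,
        "supply_flow_lpm": 7.0,
        "input_side": "left",
    }


@dataclass(frozen=True)
class Phase:
    """One constant-condition interval ``[start_s, end_s)`` of the schedule."""

    start_s: float
    end_s: float
    gas: Gas
    flow: Flow

    def __post_init__(self) -> None:
        for name in ("start_s", "end_s"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be a non-negative finite time, got {v!r}")
        if not self.start_s < self.end_s:
            raise ValueError(
                f"phase must have start_s < end_s, got [{self.start_s}, {self.end_s})"
            )
        object.__setattr__(self, "gas", Gas(self.gas))
        object.__setattr__(self, "flow", Flow(self.flow))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Protocol:
    """An ordered, contiguous phase schedule plus the frame clock."""

    phases: tuple[Phase, ...]
    frame_interval_s: float = 1.5
    metadata: Mapping[str, Any] = field(default_factory=_default_metadata)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.phases:
            if self.phases[0].start_s != 0.0:
                raise ValueError("first phase must start at t = 0")
            for a, b in zip(self.phases, self.phases[1:]):
                if a.end_s != b.start_s:
                    raise ValueError(
                        f"phases must be contiguous: [{a.start_s},{a.end_s}) then "
                        f"[{b.start_s},{b.end_s})"
                    )

    @property
    def duration_s(self) -> float:
        return self.phases[-1].end_s if self.phases else 0.0

    def to_dict(self) -> dict[str, Any]:
        """Plain-data form suitable for a YAML/JSON config block."""
        return {
            "phases": [
                {
                    "start_s": p.start_s,
                    "end_s": p.end_s,
                    "gas": p.gas.value,
                    "flow": p.flow.value,
                }
                for p in self.phases
            ],
            "frame_interval_s": self.frame_interval_s,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Protocol":
        phases = tuple(
            Phase(p["start_s"], p["end_s"], Gas(p["gas"]), Flow(p["flow"]))
            for p in d["phases"]
        )
        meta = dict(_default_metadata())
        meta.update(d.get("metadata", {}))
        return cls(phases, float(d.get("frame_interval_s", 1.5)), meta)


#: Published schedules keyed by variant name.
PROTOCOL_VARIANTS = ("pre_fess", "post_fess")

_PRE_FESS_PHASES = (
    Phase(0.0, 10.5, Gas.AIR, Flow.LAMINAR),
    Phase(10.5, 34.5, Gas.XENON, Flow.LAMINAR),
    Phase(34.5, 52.5, Gas.XENON, Flow.PULSATING),
    Phase(52.5, 63.0, Gas.AIR, Flow.LAMINAR),
    Phase(63.0, 69.0, Gas.AIR, Flow.PULSATING),
)

# Post-surgery run: xenon supply was stopped around 50 s; the schedule is
# pinned to the 33-frame acquisition, i.e. 33 * 1.5 s = 49.5 s.
_POST_FESS_PHASES = (
    Phase(0.0, 10.5, Gas.AIR, Flow.LAMINAR),
    Phase(10.5, 34.5, Gas.XENON, Flow.LAMINAR),
    Phase(34.5, 49.5, Gas.XENON, Flow.PULSATING),
)


def build_protocol(variant: str) -> Protocol:
    """Return the fixed published schedule for ``variant``.

    Parameters
    ----------
    variant
        ``"pre_fess"`` (intact sinuses, 69 s with washout) or
        ``"post_fess"`` (after functional endoscopic sinus surgery, 49.5 s).

    Raises
    ------
    UnknownVariantError
        If ``variant`` is not one of the two published schedules.
    """
    if variant == "pre_fess":
        return Protocol(_PRE_FESS_PHASES)
    if variant == "post_fess":
        return Protocol(_POST_FESS_PHASES)
    raise UnknownVariantError(
        f"unknown protocol variant {variant!r}; expected one of {PROTOCOL_VARIANTS}"
    )


def frame_times(protocol: Protocol) -> np.ndarray:
    """Frame timestamps ``k * dt`` for ``k = 0 .. N-1``, ``N = floor(T / dt)``.

    The pre-surgery schedule (69 s at 1.5 s) yields 46 frames ending at
    67.5 s; the post-surgery schedule yields 33 frames.
    """
    if not protocol.phases:
        return np.empty(0, dtype=float)
    dt = protocol.frame_interval_s
    n = int(math.floor(protocol.duration_s / dt + 1e-9))
    return np.arange(n, dtype=float) * dt


def phase_at(protocol: Protocol, t: float) -> Phase:
    """The unique phase whose half-open interval contains time ``t``.

    Raises
    ------
    TimeOutOfRangeError
        If ``t`` lies outside ``[0, duration)``.
    """
    if not protocol.phases or not (0.0 <= t < protocol.duration_s):
        raise TimeOutOfRangeError(
            f"t = {t} s outside protocol span [0, {protocol.duration_s}) s"
        )
    for p in protocol.phases:
        if p.start_s <= t < p.end_s:
            return p
    raise TimeOutOfRangeError(f"no phase covers t = {t} s")  # pragma: no cover


def first_gas_onset(protocol: Protocol, gas: Gas = Gas.XENON) -> float:
    """Start time of the first phase delivering ``gas``; raises if absent."""
    for p in protocol.phases:
        if p.gas == gas:
            return p.start_s
    raise TimeOutOfRangeError(f"protocol has no {gas.value} phase")


def phase_onsets(protocol: Protocol, gas: Gas | None = None,
                 flow: Flow | None = None) -> list[float]:
    """Start times of phases matching the given gas and/or flow."""
    out = []
    for p in protocol.phases:
        if (gas is None or p.gas == gas) and (flow is None or p.flow == flow):
            out.append(p.start_s)
    return out
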