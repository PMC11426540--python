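"""Treatment controllers: continuous MTD and PSA-guided adaptive therapy.

Two protocols are modelled.  Under continuous maximum tolerable dose (MTD)
the drug is simply always on.  Under Zhang-style adaptive therapy (AT) the
drug starts on, is withdrawn when serum PSA falls to half of its baseline
(t = 0) value, and is re-administered when PSA recovers to baseline — an
explicit hysteresis state machine driven by directional threshold crossings.

By convention a run only counts as adaptive therapy if the drug was actually
withdrawn at least once before competitive release; otherwise the protocol
degenerates to MTD and is reported as not applicable (N/A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Protocol",
    "TreatmentState",
    "ThresholdEvent",
    "TherapyRecord",
    "DegenerateBaselineError",
    "initial_state",
    "switching_event",
    "at_applicable",
]


class Protocol(str, Enum):
    MTD = "mtd"
    AT = "at"


class TreatmentState(str, Enum):
    ON = "on"
    OFF = "off"


class DegenerateBaselineError(ValueError):
    """Adaptive therapy requested with zero baseline PSA (thresholds undefined)."""


@dataclass(frozen=True)
class ThresholdEvent:
    """Directional zero-crossing of PSA through a threshold.

    ``direction = -1`` fires when PSA crosses the threshold from above,
    ``+1`` from below, ``0`` never (the MTD sentinel).  Calling the event
    returns the signed distance of a PSA value from the threshold, the form
    ODE event-locators expect.
    """

    threshold: float
    direction: int

    def __call__(self, psa_value: float) -> float:
        return psa_value - self.threshold


#: Sentinel for protocols that never switch: the returned function has no
#: zero on the reachable PSA range (threshold -inf) and direction 0.
NEVER_FIRES = ThresholdEvent(threshold=-math.inf, direction=0)


@dataclass
class TherapyRecord:
    """Completed treatment history of one simulated course.

    ``switch_times`` is the ordered list of (time, new_state) pairs; states
    strictly alternate and an MTD record has none.
    """

    protocol: Protocol
    baseline_psa: float
    switch_times: list[tuple[float, TreatmentState]] = field(default_factory=list)
    current_state: TreatmentState = TreatmentState.ON

    def validate(self) -> None:
        times = [t for t, _ in self.switch_times]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")
        states = [s for _, s in self.switch_times]
        if any(b == a for a, b in zip(states, states[1:])):
            raise ValueError("switch states must strictly alternate")
        if self.protocol is Protocol.MTD and self.switch_times:
            raise ValueError("MTD records cannot contain switches")

    def off_switch_times(self) -> list[float]:
        return [t for t, s in self.switch_times if s is TreatmentState.OFF]


def initial_state(protocol: Protocol) -> TreatmentState:
    """Both protocols begin with the drug on; baseline PSA is PSA at t = 0."""
    if protocol not in (Protocol.MTD, Protocol.AT):
        raise ValueError(f"unknown protocol {protocol!r}")
    return TreatmentState.ON


def switching_event(
    protocol: Protocol,
    current_state: TreatmentState,
    baseline_psa: float,
    lower_frac: float = 0.5,
    upper_frac: float = 1.0,
) -> ThresholdEvent:
    """Threshold event whose directional zero-crossing triggers a switch.

    On-treatment the event fires when PSA drops to ``lower_frac`` of baseline
    (default one half); off-treatment when it recovers to ``upper_frac`` of
    baseline (default the baseline itself).  MTD returns a never-firing
    sentinel.  Ties at t = 0 do not fire: treatment starts on regardless.
    """
    if protocol is Protocol.MTD:
        return NEVER_FIRES
    if protocol is not Protocol.AT:
        raise ValueError(f"unknown protocol {protocol!r}")
    if baseline_psa <= 0:
        raise DegenerateBaselineError(
            "adaptive therapy needs baseline PSA > 0 to define its thresholds"
        )
    if current_state is TreatmentState.ON:
        return ThresholdEvent(threshold=lower_frac * baseline_psa, direction=-1)
    return ThresholdEvent(threshold=upper_frac * baseline_psa, direction=+1)


def at_applicable(
    record: TherapyRecord, tcr: float | None, horizon: float | None = None
) -> bool:
    """Whether a completed run counts as adaptive therapy.

    True iff the drug was withdrawn (an on -> off switch) strictly before
    competitive release — or, when no release occurred, before the horizon.
    Therapy keeps cycling after release, so later switches are ignored.
    """
    if record.protocol is not Protocol.AT:
        return False
    limit = tcr if tcr is not None else (horizon if horizon is not None else math.inf)
    return any(t < limit for t in record.off_switch_times())
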