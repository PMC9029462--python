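"""Shared result types used across the analysis modules."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

#: Pharmacopoeial disintegration limit for orodispersible films, seconds.
CAP_S = 180.0

#: Where an endpoint estimate came from.
ENDPOINT_SOURCES = ("video_split", "friction_changepoint", "simulated_observation")


@dataclass(frozen=True)
class EndpointResult:
    """A disintegration endpoint, possibly right-censored at the test cap.

    ``time_s`` is the detected (or observed) disintegration time in seconds,
    and is ``None`` when the result is censored — i.e. the film never lost
    structural integrity before ``cap_s``. ``source`` records which detector
    produced the value: the video split rule, the friction change-point
    detector, or the simulated stopwatch observation.
    """

    time_s: Optional[float]
    censored: bool
    source: str
    cap_s: float = CAP_S
    detail: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.source not in ENDPOINT_SOURCES:
            raise ValueError(f"unknown endpoint source {self.source!r}")
        if self.cap_s <= 0:
            raise ValueError("cap_s must be positive")
        if self.censored:
            if self.time_s is not None:
                raise ValueError("censored result must not carry a time")
        else:
            if self.time_s is None:
                raise ValueError("non-censored result requires a time")
            if not 0 < self.time_s <= self.cap_s:
                raise ValueError("time_s must lie in (0, cap_s]")

    def render(self) -> str:
        """Human-readable value, ``'>180.0'`` style for censored results."""
        if self.censored:
            return f">{self.cap_s:.1f}"
        return f"{self.time_s:.1f}"

    def to_dict(self) -> dict:
        return {
            "time_s": self.time_s,
            "censored": self.censored,
            "cap_s": self.cap_s,
            "source": self.source,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "EndpointResult":
        return cls(
            time_s=d["time_s"],
            censored=bool(d["censored"]),
            source=d["source"],
            cap_s=float(d.get("cap_s", CAP_S)),
        )
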