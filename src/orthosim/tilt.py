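"""Tilt-table posture schedules.

The tilt angle alpha(t) follows a cosinusoidal ramp between the start and end
angles: smooth (C^1) at both ends, with a mean slope over the ramp equal to the
requested tilting rate, so the ramp duration is |alpha_end - alpha_start| / rate.
A linear ramp is available as a sensitivity option.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class TiltSchedule:
    """Posture as a function of time.

    Angles in degrees (0 = supine, 90 = upright), rate in deg/s. The schedule
    holds ``alpha_start`` until ``t_start``, ramps over ``ramp_duration`` and
    holds ``alpha_end`` afterwards. Tilt-down uses ``alpha_end < alpha_start``
    unchanged.
    """

    alpha_start: float
    alpha_end: float
    mean_rate: float
    t_start: float = 0.0
    shape: str = "cosine"  # or "linear"
    pre_hold: float = 0.0
    post_hold: float = 0.0
    ramp_duration: float = field(init=False)

    def __post_init__(self):
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive (deg/s)")
        for a in (self.alpha_start, self.alpha_end):
            if not 0.0 <= a <= 90.0:
                raise ValueError(f"tilt angle {a} outside [0, 90] deg")
        if self.shape not in ("cosine", "linear"):
            raise ValueError(f"unknown ramp shape {self.shape!r}")
        object.__setattr__(
            self, "ramp_duration",
            abs(self.alpha_end - self.alpha_start) / self.mean_rate)

    def angle(self, t: float) -> float:
        return tilt_angle(t, self)

    @property
    def t_end(self) -> float:
        return self.t_start + self.ramp_duration


def tilt_angle(t: float, sched: TiltSchedule) -> float:
    """Tilt angle in degrees at time ``t`` for the given schedule."""
    if t <= sched.t_start:
        return sched.alpha_start
    if sched.ramp_duration == 0.0 or t >= sched.t_start + sched.ramp_duration:
        return sched.alpha_end
    s = (t - sched.t_start) / sched.ramp_duration
    if sched.shape == "linear":
        w = s
    else:
        w = 0.5 * (1.0 - math.cos(math.pi * s))
    return sched.alpha_start + (sched.alpha_end - sched.alpha_start) * w


def build_protocol(config: dict) -> list[TiltSchedule]:
    """Build one schedule per requested (angle, rate, direction) combination.

    ``config`` keys: ``angles`` (deg), ``rates`` (deg/s), ``direction``
    ('up', 'down' or 'both'), optional ``t_start``, ``shape``, ``pre_hold``,
    ``post_hold``. Supports the tilting-rate sweep {35, 8, 4, 2.5, 1.4} deg/s
    and angles {30, 70, 90}.
    """
    angles = config.get("angles", [70.0])
    rates = config.get("rates", [4.0])
    direction = config.get("direction", "up")
    t_start = config.get("t_start", 0.0)
    shape = config.get("shape", "cosine")
    pre_hold = config.get("pre_hold", 0.0)
    post_hold = config.get("post_hold", 0.0)
    dirs = {"up": [("up")], "down": ["down"], "both": ["up", "down"]}[direction]
    schedules = []
    for angle in angles:
        for rate in rates:
            if rate <= 0 or rate > 90:
                raise ValueError(f"tilting rate {rate} deg/s outside (0, 90]")
            for d in dirs:
                a0, a1 = (0.0, angle) if d == "up" else (angle, 0.0)
                schedules.append(TiltSchedule(
                    alpha_start=a0, alpha_end=a1, mean_rate=rate,
                    t_start=t_start, shape=shape,
                    pre_hold=pre_hold, post_hold=post_hold))
    return schedules
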