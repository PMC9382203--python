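"""Step-wise thermal-ramping protocol and its measurement schedule.

The acute warming protocol starts at an acclimation temperature (10°C), holds
an initial measurement plateau there, then ramps step-wise through a list of
target temperatures. Nominal heating rates are expressed per protocol segment
*including* the measurement plateau at the segment's target: at a nominal
5°C h⁻¹ the 10→15°C segment lasts 60 min, i.e. a 40-min linear ramp followed
by a 20-min plateau during which respirometry cycles run. Beyond 20°C the
nominal rate drops to 2°C h⁻¹ with a plateau at every step.

Each plateau carries ``cycles_per_plateau`` intermittent-flow respirometry
cycles (a sealed "closed" measurement phase followed by a flush). Closed
phases must fit inside the constant-temperature plateau; the final flush of a
plateau may overhang into the next ramp, which is how three 3+5-min cycles
fit a 20-min plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

DEFAULT_STEP_TARGETS = (15.0, 20.0, 22.0, 23.0, 24.0, 25.0, 26.0, 27.0, 28.0, 29.0)

__all__ = [
    "RampProtocol",
    "MeasurementCycle",
    "Phase",
    "generate_temperature_profile",
    "default_protocol",
]


@dataclass(frozen=True)
class Phase:
    """One contiguous piece of the temperature schedule."""

    kind: str  # "ramp" or "plateau"
    t0_s: float
    t1_s: float
    temp0: float
    temp1: float
    step_temp: float | None = None  # set for plateaus


@dataclass(frozen=True)
class MeasurementCycle:
    """One closed+flush respirometry cycle, times in seconds from protocol start."""

    step_temp: float
    index: int  # 0-based within its plateau
    closed_start_s: float
    closed_end_s: float
    flush_start_s: float
    flush_end_s: float


@dataclass(frozen=True)
class RampProtocol:
    """Temperature schedule, plateaus and respirometry cycle layout.

    Parameters
    ----------
    start_temp : °C, acclimation temperature (default 10).
    step_targets : ordered measurement temperatures, °C.
    ramp_rates : nominal °C h⁻¹ per segment, plateau time included (see module
        docstring). Defaults to 5 up to 20°C and 2 above.
    plateau_duration : min held at each target (and at the start temperature).
    cycles_per_plateau : respirometry cycles per plateau.
    closed_phase, flush_phase : cycle phase durations, min (2–5 and 5–8).
    blood_sample_temps : steps at whose plateau end a venous sample is drawn;
        an additional sample is always taken at loss of equilibrium.
    """

    start_temp: float = 10.0
    step_targets: tuple[float, ...] = DEFAULT_STEP_TARGETS
    ramp_rates: tuple[float, ...] | None = None
    plateau_duration: float = 20.0
    cycles_per_plateau: int = 3
    closed_phase: float = 3.0
    flush_phase: float = 5.0
    blood_sample_temps: tuple[float, ...] = (10.0, 20.0, 24.0, 26.0)

    def __post_init__(self) -> None:
        targets = tuple(float(t) for t in self.step_targets)
        object.__setattr__(self, "step_targets", targets)
        if not targets:
            raise ConfigurationError("step_targets must be non-empty")
        prev = self.start_temp
        for t in targets:
            if t <= prev:
                raise ConfigurationError(
                    f"step_targets must be strictly increasing from start_temp; got {t} after {prev}"
                )
            prev = t
        if self.ramp_rates is None:
            rates = tuple(5.0 if t <= 20.0 else 2.0 for t in targets)
            object.__setattr__(self, "ramp_rates", rates)
        else:
            rates = tuple(float(r) for r in self.ramp_rates)
            object.__setattr__(self, "ramp_rates", rates)
        if len(self.ramp_rates) != len(targets):
            raise ConfigurationError("ramp_rates must match step_targets length")
        if any(r <= 0 for r in self.ramp_rates):
            raise ConfigurationError("ramp_rates must be positive")
        if not 2.0 <= self.closed_phase <= 5.0:
            raise ConfigurationError("closed_phase must be within 2–5 min")
        if not 5.0 <= self.flush_phase <= 8.0:
            raise ConfigurationError("flush_phase must be within 5–8 min")
        if self.cycles_per_plateau < 1:
            raise ConfigurationError("cycles_per_plateau must be >= 1")
        needed = (
            self.cycles_per_plateau * self.closed_phase
            + (self.cycles_per_plateau - 1) * self.flush_phase
        )
        if needed > self.plateau_duration + 1e-9:
            raise ConfigurationError(
                f"{self.cycles_per_plateau} cycles of {self.closed_phase}+{self.flush_phase} min "
                f"do not fit a {self.plateau_duration}-min plateau "
                f"(need {needed} min of closed phases inside the plateau)"
            )
        # Validate every ramp duration up front.
        for i in range(len(targets)):
            self.ramp_minutes(i)
        bad = [
            t
            for t in self.blood_sample_temps
            if t != self.start_temp and t not in targets
        ]
        if bad:
            raise ConfigurationError(
                f"blood_sample_temps must be protocol temperatures; unknown: {bad}"
            )

    # -- schedule geometry ---------------------------------------------------

    def ramp_minutes(self, segment: int) -> float:
        """Ramp duration (min) for segment ``segment`` (to step_targets[segment])."""
        t0 = self.start_temp if segment == 0 else self.step_targets[segment - 1]
        span = self.step_targets[segment] - t0
        if span == 0:
            return 0.0
        nominal = span / self.ramp_rates[segment] * 60.0
        ramp = nominal - self.plateau_duration
        if ramp < 0:
            raise ConfigurationError(
                f"segment to {self.step_targets[segment]}°C: nominal duration "
                f"{nominal:.1f} min at {self.ramp_rates[segment]}°C/h is shorter than the "
                f"{self.plateau_duration}-min plateau"
            )
        return ramp

    def phases(self) -> list[Phase]:
        """Full schedule as alternating plateau/ramp phases (seconds)."""
        out: list[Phase] = []
        t = 0.0
        plat_s = self.plateau_duration * 60.0
        out.append(Phase("plateau", t, t + plat_s, self.start_temp, self.start_temp, self.start_temp))
        t += plat_s
        prev_temp = self.start_temp
        for i, target in enumerate(self.step_targets):
            ramp_s = self.ramp_minutes(i) * 60.0
            out.append(Phase("ramp", t, t + ramp_s, prev_temp, target))
            t += ramp_s
            out.append(Phase("plateau", t, t + plat_s, target, target, target))
            t += plat_s
            prev_temp = target
        return out

    @property
    def total_duration_s(self) -> float:
        return self.phases()[-1].t1_s

    @property
    def step_temps(self) -> tuple[float, ...]:
        """All measurement temperatures, start temperature included."""
        return (self.start_temp,) + self.step_targets

    def measurement_cycles(self) -> list[MeasurementCycle]:
        """Respirometry cycles for every plateau, in protocol order."""
        cyc_s = (self.closed_phase + self.flush_phase) * 60.0
        closed_s = self.closed_phase * 60.0
        flush_s = self.flush_phase * 60.0
        cycles: list[MeasurementCycle] = []
        for ph in self.phases():
            if ph.kind != "plateau":
                continue
            for k in range(self.cycles_per_plateau):
                c0 = ph.t0_s + k * cyc_s
                cycles.append(
                    MeasurementCycle(
                        step_temp=ph.step_temp,
                        index=k,
                        closed_start_s=c0,
                        closed_end_s=c0 + closed_s,
                        flush_start_s=c0 + closed_s,
                        flush_end_s=c0 + closed_s + flush_s,
                    )
                )
        return cycles

    def blood_sample_times(self) -> list[tuple[float, float]]:
        """(step_temp, time_s) pairs: samples are drawn at plateau end."""
        out = []
        for ph in self.phases():
            if ph.kind == "plateau" and ph.step_temp in self.blood_sample_temps:
                out.append((ph.step_temp, ph.t1_s))
        return out

    def temperature_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints (time_s, temp_C) of the piecewise-linear schedule."""
        ts, temps = [0.0], [self.start_temp]
        for ph in self.phases():
            ts.append(ph.t1_s)
            temps.append(ph.temp1)
        return np.asarray(ts), np.asarray(temps)


def default_protocol() -> RampProtocol:
    """The study protocol: 10°C start, plateaus at 15, 20, 22 then every 1°C."""
    return RampProtocol()


def generate_temperature_profile(
    protocol: RampProtocol, dt: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the temperature schedule on a regular grid.

    Returns ``(time_s, temp_C)`` arrays; the profile is piecewise linear,
    monotone non-decreasing, with flat plateaus at each step target.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    knots_t, knots_temp = protocol.temperature_knots()
    t = np.arange(0.0, protocol.total_duration_s + dt * 0.5, dt)
    return t, np.interp(t, knots_t, knots_temp)
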