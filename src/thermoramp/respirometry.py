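"""Water-O2 traces → QC'd, background-corrected, mass-specific MO2.

The intermittent-flow pipeline: segment the trace into sealed ("closed")
measurement phases using the event log, fit an ordinary least-squares line to
the O2 concentration decline in each phase, subtract the temperature-
interpolated background slope, convert to mass-specific O2 uptake, then
summarise per temperature step (routine MO2 = mean of the cycles at a step)
and across steps (maximal routine MO2).

Sign convention: slopes are concentration change per minute, so a fish
signal is negative. The background slope is *subtracted* from the measured
slope — a positive background (apparent O2 gain from chamber warming) makes
the fish-attributed decline steeper, a negative one (microbial uptake) makes
it shallower.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .units import airsat_to_mgL

__all__ = [
    "SlopeFit",
    "BackgroundModel",
    "MO2Record",
    "DEFAULT_R2_MIN",
    "segment_cycles",
    "fit_slope",
    "background_correct",
    "compute_mo2",
    "routine_mo2",
    "max_routine_mo2",
    "process_fish",
]

#: Default R² gate for accepting a closed-phase slope.
DEFAULT_R2_MIN = 0.95

#: Minimum samples for a usable closed-phase segment.
MIN_SEGMENT_SAMPLES = 10


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of O2 concentration (mg L⁻¹) against time (min)."""

    slope: float  # mg O2 L^-1 min^-1
    intercept: float  # mg O2 L^-1 at segment start
    r_squared: float  # NaN when the response is degenerate
    n_points: int
    mean_temp: float  # °C
    qc_pass: bool


@dataclass(frozen=True)
class BackgroundModel:
    """Background chamber slope (mg O2 L⁻¹ min⁻¹), linear in temperature.

    Anchored at the slope measured at the protocol start temperature and at
    the CTmax temperature; evaluates exactly to the anchors there.
    """

    temp_start: float
    slope_at_start: float
    temp_end: float
    slope_at_end: float

    def __post_init__(self) -> None:
        if self.temp_end == self.temp_start:
            raise AnalysisError("background anchors need two distinct temperatures")

    @property
    def coefficients(self) -> tuple[float, float]:
        """(intercept, slope-per-°C) of the background line."""
        b = (self.slope_at_end - self.slope_at_start) / (self.temp_end - self.temp_start)
        a = self.slope_at_start - b * self.temp_start
        return a, b

    def __call__(self, temp_c):
        a, b = self.coefficients
        out = a + b * np.asarray(temp_c, dtype=float)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MO2Record:
    """One background-corrected measurement cycle."""

    temp_step: float
    cycle_index: int
    mo2: float  # mg O2 kg^-1 h^-1; negative values are flagged, never clipped
    fit: SlopeFit
    corrected_slope: float
    anomalous: bool  # True when the corrected uptake came out negative


@dataclass(frozen=True)
class Segment:
    """A closed-phase slice of the trace, labelled with its protocol step."""

    step_temp: float
    cycle_index: int
    t0_s: float
    t1_s: float
    data: pd.DataFrame  # time_s, temp_C, o2_airsat_pct


def segment_cycles(
    trace: pd.DataFrame, events: pd.DataFrame, step_temps
) -> list[Segment]:
    """Slice the trace into closed-phase segments from the event log.

    Closed phases are defined by matched ``closed_start``/``closed_end``
    pairs; each segment is labelled with the protocol step nearest its mean
    temperature and indexed by its position within that step.
    """
    steps = np.asarray(sorted(step_temps), dtype=float)
    starts = events.loc[events["event"] == "closed_start", "time_s"].to_numpy()
    ends = events.loc[events["event"] == "closed_end", "time_s"].to_numpy()
    if len(starts) != len(ends):
        raise AnalysisError(
            f"unmatched closed-phase events: {len(starts)} starts, {len(ends)} ends"
        )
    t = trace["time_s"].to_numpy()
    out: list[Segment] = []
    counter: dict[float, int] = {}
    for t0, t1 in zip(np.sort(starts), np.sort(ends)):
        if t1 <= t0:
            raise AnalysisError(f"closed phase ends before it starts: {t0}..{t1}")
        mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        sub = trace.loc[mask]
        if len(sub) == 0:
            raise AnalysisError(f"closed phase {t0}..{t1} covers no trace samples")
        if len(sub) < MIN_SEGMENT_SAMPLES:
            raise AnalysisError(
                f"closed phase {t0}..{t1} has only {len(sub)} samples "
                f"(need >= {MIN_SEGMENT_SAMPLES})"
            )
        mean_temp = float(sub["temp_C"].mean())
        step = float(steps[np.argmin(np.abs(steps - mean_temp))])
        idx = counter.get(step, 0)
        counter[step] = idx + 1
        out.append(Segment(step, idx, float(t0), float(t1), sub))
    return out


def fit_slope(segment: Segment, r2_min: float = DEFAULT_R2_MIN) -> SlopeFit:
    """OLS fit of O2 concentration versus time over one closed phase.

    QC passes when R² ≥ ``r2_min``; a flat (zero-variance) response leaves R²
    undefined (NaN) and fails QC explicitly rather than erroring.
    """
    sub = segment.data
    if len(sub) < 3:
        raise AnalysisError("need at least 3 samples to fit a slope")
    t_min = (sub["time_s"].to_numpy() - sub["time_s"].iloc[0]) / 60.0
    conc = np.asarray(airsat_to_mgL(sub["o2_airsat_pct"].to_numpy(), sub["temp_C"].to_numpy()))
    sxx = float(np.sum((t_min - t_min.mean()) ** 2))
    if sxx == 0.0:
        raise AnalysisError("degenerate time axis in closed phase")
    sxy = float(np.sum((t_min - t_min.mean()) * (conc - conc.mean())))
    slope = sxy / sxx
    intercept = float(conc.mean() - slope * t_min.mean())
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = float("nan")
        qc = False
    else:
        resid = conc - (intercept + slope * t_min)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        qc = bool(r2 >= r2_min)
    return SlopeFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(sub),
        mean_temp=float(sub["temp_C"].mean()),
        qc_pass=qc,
    )


def background_correct(raw: SlopeFit, bg: BackgroundModel) -> float:
    """Fish-attributed slope: measured slope minus the background at the
    cycle's mean temperature."""
    return raw.slope - float(bg(raw.mean_temp))


def compute_mo2(
    corrected_slope: float, fish_mass_kg: float, respirometer_volume_l: float
) -> float:
    """Mass-specific O2 uptake (mg O2 kg⁻¹ h⁻¹) from a corrected slope.

    ``mo2 = −slope · 60 · (V − mass/1.0) / mass`` with the fish displacing
    water at density 1.0 kg L⁻¹. Negative results propagate (flagged by the
    caller), they are not clipped.
    """
    v_eff = respirometer_volume_l - fish_mass_kg / 1.0
    if v_eff <= 0:
        raise AnalysisError("non-positive effective respirometer volume")
    if fish_mass_kg <= 0:
        raise AnalysisError("fish mass must be positive")
    return -corrected_slope * 60.0 * v_eff / fish_mass_kg


def routine_mo2(records: list[MO2Record]) -> tuple[float | None, int]:
    """Routine MO2 at one step: mean over QC-passing cycles.

    Returns ``(mean, n_used)``; when every cycle fails QC the value is None
    and a warning is emitted.
    """
    passing = [r.mo2 for r in records if r.fit.qc_pass]
    if not passing:
        warnings.warn(
            f"all {len(records)} cycles failed QC at step "
            f"{records[0].temp_step if records else '?'}; routine MO2 missing",
            stacklevel=2,
        )
        return None, 0
    return float(np.mean(passing)), len(passing)


def max_routine_mo2(step_means: dict[float, float]) -> tuple[float, float]:
    """(value, temperature) of the highest routine MO2 over steps.

    Ties break toward the higher temperature.
    """
    if not step_means:
        raise AnalysisError("no steps with a routine MO2 value")
    best_temp = max(step_means, key=lambda s: (step_means[s], s))
    return step_means[best_temp], best_temp


def process_fish(
    trace: pd.DataFrame,
    events: pd.DataFrame,
    *,
    fish_mass_kg: float,
    respirometer_volume_l: float,
    background: BackgroundModel,
    step_temps,
    r2_min: float = DEFAULT_R2_MIN,
) -> tuple[list[MO2Record], pd.DataFrame, pd.DataFrame]:
    """Full respirometry stage for one fish.

    Returns ``(records, records_df, summary_df)`` where the summary has one
    row per step (step, mo2_rou, n_cycles_used, is_max).
    """
    segments = segment_cycles(trace, events, step_temps)
    records: list[MO2Record] = []
    for seg in segments:
        fit = fit_slope(seg, r2_min)
        corrected = background_correct(fit, background)
        mo2 = compute_mo2(corrected, fish_mass_kg, respirometer_volume_l)
        records.append(
            MO2Record(
                temp_step=seg.step_temp,
                cycle_index=seg.cycle_index,
                mo2=mo2,
                fit=fit,
                corrected_slope=corrected,
                anomalous=bool(mo2 < 0),
            )
        )
    records_df = pd.DataFrame(
        {
            "step": [r.temp_step for r in records],
            "cycle": [r.cycle_index for r in records],
            "slope": [r.fit.slope for r in records],
            "corrected_slope": [r.corrected_slope for r in records],
            "r2": [r.fit.r_squared for r in records],
            "qc_pass": [r.fit.qc_pass for r in records],
            "mo2": [r.mo2 for r in records],
            "anomalous": [r.anomalous for r in records],
        }
    )
    by_step: dict[float, list[MO2Record]] = {}
    for r in records:
        by_step.setdefault(r.temp_step, []).append(r)
    means: dict[float, float] = {}
    counts: dict[float, int] = {}
    for step, recs in by_step.items():
        m, n = routine_mo2(recs)
        if m is not None:
            means[step] = m
            counts[step] = n
    if means:
        _, max_step = max_routine_mo2(means)
    else:
        max_step = None
    summary = pd.DataFrame(
        {
            "step": sorted(means),
            "mo2_rou": [means[s] for s in sorted(means)],
            "n_cycles_used": [counts[s] for s in sorted(means)],
            "is_max": [s == max_step for s in sorted(means)],
        }
    )
    return records, records_df, summary
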