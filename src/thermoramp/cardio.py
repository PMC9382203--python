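"""Pulsatile flow → heart rate, cardiac output, stroke volume, Fick A-V O2.

Cardiac variables are computed on the same closed-phase windows as the MO2
measurements ("tied" windows): routine values per temperature step are the
mean over that step's measurement cycles, and the reported maxima are the
values at the step where the maximal routine MO2 occurred — even if cardiac
output happens to be numerically higher at some other step.

Units: cardiac output is mass-specific (ml min⁻¹ kg⁻¹) and stroke volume is
therefore carried mass-specific too (ml beat⁻¹ kg⁻¹; multiply by body mass
for the absolute ml beat⁻¹ form). The Fick-estimated A-V O2 content
difference is MO2 / (60·CO) in mg O2 ml⁻¹; the mass terms cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import AnalysisError, NoBeatsError

__all__ = [
    "CardiacWindow",
    "detect_beats",
    "heart_rate",
    "cardiac_output",
    "stroke_volume",
    "fick_avo2",
    "tie_windows",
]

#: Default peak prominence as a fraction of the window's amplitude range.
DEFAULT_PROMINENCE_FRAC = 0.3

#: Refractory period = 60 / (REFRACTORY_HR_FACTOR × running HR estimate) s.
REFRACTORY_HR_FACTOR = 2.5

#: Minimum analysis window, s.
MIN_WINDOW_S = 30.0


@dataclass(frozen=True)
class CardiacWindow:
    """Cardiac variables over one MO2 measurement interval (or their per-step
    mean), tied to a routine MO2 value when one is available."""

    t0_s: float
    t1_s: float
    temp_step: float
    heart_rate: float  # beats min^-1
    cardiac_output: float  # ml min^-1 kg^-1
    stroke_volume: float  # ml beat^-1 kg^-1
    avo2: float | None  # mg O2 ml^-1
    tied_mo2: float | None  # mg O2 kg^-1 h^-1
    is_max_window: bool = False
    incomplete: bool = False


def detect_beats(
    times: np.ndarray,
    flow: np.ndarray,
    *,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    refractory_hr_factor: float = REFRACTORY_HR_FACTOR,
) -> np.ndarray:
    """Systolic peak times within one window.

    Two passes of local-maximum detection: a prominence-only pass yields a
    running heart-rate estimate, from which a refractory period (distance)
    suppresses noise peaks in the second pass.
    """
    times = np.asarray(times, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if len(times) < 2:
        raise AnalysisError("window too short for beat detection")
    span = times[-1] - times[0]
    if span < MIN_WINDOW_S:
        raise AnalysisError(f"beat-detection window must span >= {MIN_WINDOW_S} s")
    amp_range = float(flow.max() - flow.min())
    if amp_range <= 0:
        raise NoBeatsError("flat flow signal: no pulses to detect")
    prom = prominence_frac * amp_range
    peaks, _ = find_peaks(flow, prominence=prom)
    if len(peaks) < 2:
        raise NoBeatsError("fewer than two pulses detected in window")
    dt = float(np.median(np.diff(times)))
    median_interval = float(np.median(np.diff(times[peaks])))  # s per beat
    hr_estimate = 60.0 / median_interval  # bpm
    refractory_s = 60.0 / (refractory_hr_factor * hr_estimate)
    distance = max(1, int(round(refractory_s / dt)))
    peaks, _ = find_peaks(flow, prominence=prom, distance=distance)
    if len(peaks) < 2:
        raise NoBeatsError("fewer than two pulses detected in window")
    return times[peaks]


def heart_rate(beat_times: np.ndarray) -> float:
    """Beats min⁻¹ from the first-to-last beat span: 60·(n−1)/(t_n − t_1)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < 2:
        raise AnalysisError("need at least two beats for a heart rate")
    span = beat_times[-1] - beat_times[0]
    if span <= 0:
        raise AnalysisError("beat times must be strictly increasing")
    return 60.0 * (len(beat_times) - 1) / span


def cardiac_output(flow: np.ndarray, fish_mass_kg: float) -> float:
    """Mass-specific cardiac output: time-mean flow over the window ÷ mass."""
    flow = np.asarray(flow, dtype=float)
    if len(flow) == 0:
        raise AnalysisError("empty flow window")
    if fish_mass_kg <= 0:
        raise AnalysisError("fish mass must be positive")
    return float(flow.mean()) / fish_mass_kg


def stroke_volume(co: float, hr: float) -> float:
    """ml beat⁻¹ kg⁻¹ = cardiac output / heart rate."""
    if hr <= 0:
        raise AnalysisError("heart rate must be positive")
    return co / hr


def fick_avo2(mo2: float, co: float) -> float:
    """A-V O2 content difference (mg O2 ml⁻¹) = MO2 / (60·CO).

    MO2 is per hour, CO per minute; both mass-specific, so mass cancels.
    """
    if co <= 0:
        raise AnalysisError("cardiac output must be positive")
    return mo2 / (co * 60.0)


def tie_windows(
    trace: pd.DataFrame,
    cycle_intervals: list[tuple[float, float, float]],
    mo2_by_step: dict[float, float],
    *,
    fish_mass_kg: float,
    max_step: float | None = None,
) -> tuple[list[CardiacWindow], pd.DataFrame]:
    """Routine cardiac windows per step, tied to the MO2 measurement cycles.

    Parameters
    ----------
    trace : DataFrame with ``time_s`` and ``flow_mL_min``.
    cycle_intervals : (step_temp, t0_s, t1_s) closed-phase intervals.
    mo2_by_step : routine MO2 per step (from the respirometry stage).
    max_step : the step where maximal routine MO2 occurred; that window is
        flagged ``is_max_window`` regardless of where CO peaks.

    Returns the per-step windows plus a tidy DataFrame
    (step, hr, co, sv, avo2, tied_mo2, is_max_window, incomplete).
    """
    t = trace["time_s"].to_numpy()
    f = trace["flow_mL_min"].to_numpy()
    by_step: dict[float, list[tuple[float, float]]] = {}
    for step, t0, t1 in cycle_intervals:
        by_step.setdefault(float(step), []).append((t0, t1))

    windows: list[CardiacWindow] = []
    for step in sorted(by_step):
        hrs, cos = [], []
        incomplete = False
        covered = False
        t0s, t1s = [], []
        for t0, t1 in by_step[step]:
            mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
            if not mask.any() or t[mask][0] > t0 + 1.0 or t[mask][-1] < t1 - 1.0:
                incomplete = True
                if not mask.any():
                    continue
            covered = True
            try:
                beats = detect_beats(t[mask], f[mask])
            except AnalysisError:
                incomplete = True
                continue
            hrs.append(heart_rate(beats))
            cos.append(cardiac_output(f[mask], fish_mass_kg))
            t0s.append(t0)
            t1s.append(t1)
        if not hrs:
            if covered:
                # Some coverage existed but no cycle was usable: keep the
                # window visible, flagged, with undefined values.
                windows.append(
                    CardiacWindow(
                        t0_s=by_step[step][0][0], t1_s=by_step[step][-1][1],
                        temp_step=step, heart_rate=float("nan"),
                        cardiac_output=float("nan"), stroke_volume=float("nan"),
                        avo2=None, tied_mo2=mo2_by_step.get(step),
                        is_max_window=False, incomplete=True,
                    )
                )
            continue
        hr = float(np.mean(hrs))
        co = float(np.mean(cos))
        sv = stroke_volume(co, hr)
        mo2 = mo2_by_step.get(step)
        avo2 = fick_avo2(mo2, co) if mo2 is not None else None
        windows.append(
            CardiacWindow(
                t0_s=min(t0s), t1_s=max(t1s), temp_step=step,
                heart_rate=hr, cardiac_output=co, stroke_volume=sv,
                avo2=avo2, tied_mo2=mo2,
                is_max_window=(max_step is not None and step == max_step),
                incomplete=incomplete,
            )
        )
    df = pd.DataFrame(
        {
            "step": [w.temp_step for w in windows],
            "hr": [w.heart_rate for w in windows],
            "co": [w.cardiac_output for w in windows],
            "sv": [w.stroke_volume for w in windows],
            "avo2": [w.avo2 for w in windows],
            "tied_mo2": [w.tied_mo2 for w in windows],
            "is_max_window": [w.is_max_window for w in windows],
            "incomplete": [w.incomplete for w in windows],
        }
    )
    return windows, df
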