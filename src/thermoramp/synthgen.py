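"""Synthetic cardiorespiratory thermal-ramping trials with known ground truth.

This module emulates the raw data stream of an acute-warming experiment on
instrumented fish held in intermittent-flow respirometers: a 10 Hz water-O2
channel (% air saturation) contaminated by a temperature-dependent background
slope, a 10 Hz pulsatile ventral-aortic flow channel, a temperature channel,
an event log of closed/flush valve cycles, venous blood panels, and a
per-fish loss-of-equilibrium (CTmax) event. Every trial carries a
ground-truth sidecar so the downstream analysis stages can be tested as
parameter-recovery problems.

Default phenotypes are calibrated so the two treatment arms (normoxia at
~97% air saturation, hyperoxia at ~209%) diverge beyond ~23°C: maximal
routine MO2 plateaus of 292.8 vs 462.1 mg O2 kg⁻¹ h⁻¹, a +33% cardiac-output
and +46% stroke-volume contrast at the maximal-MO2 window (heart rate nearly
unchanged), a CTmax separation of +0.87°C, and a lactate rise near CTmax
that is attenuated under hyperoxia.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError, SimulationError
from .protocol import RampProtocol, default_protocol, generate_temperature_profile
from .units import o2_saturation_mgL

__all__ = [
    "MO2Curve",
    "HRCurve",
    "BloodParams",
    "CTmaxDist",
    "BackgroundParams",
    "FishPhenotype",
    "PopulationVariation",
    "CohortConfig",
    "FishTrial",
    "Cohort",
    "default_phenotype",
    "sample_phenotype",
    "draw_ctmax",
    "generate_o2_trace",
    "generate_flow_trace",
    "generate_blood_samples",
    "generate_fish_trial",
    "generate_cohort",
    "write_cohort",
]

#: Time constant (s) of the chamber's return to the O2 set-point while flushing.
FLUSH_TAU_S = 45.0

#: Minimum samples per heartbeat for the pulse to be resolvable at the trace rate.
MIN_SAMPLES_PER_BEAT = 4.0

GROUPS = ("normoxia", "hyperoxia")


# ---------------------------------------------------------------------------
# Phenotype building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MO2Curve:
    """Routine whole-animal O2 uptake (mg O2 kg⁻¹ h⁻¹) versus temperature.

    Exponential (Q10-style) rise from ``base10`` at 10°C; beyond
    ``divergence_temp`` the curve accelerates (hyperoxia) or continues
    (normoxia) toward a treatment-specific ``peak`` reached at ``peak_temp``,
    then stays flat — metabolic capacity saturates approaching CTmax.
    """

    base10: float
    q10: float
    divergence_temp: float
    peak: float
    peak_temp: float

    def __call__(self, temp_c):
        t = np.asarray(temp_c, dtype=float)
        v_div = self.base10 * self.q10 ** ((self.divergence_temp - 10.0) / 10.0)
        below = self.base10 * self.q10 ** ((t - 10.0) / 10.0)
        frac = np.clip(
            (t - self.divergence_temp) / (self.peak_temp - self.divergence_temp), 0.0, 1.0
        )
        mid = v_div * (self.peak / v_div) ** frac
        out = np.where(t <= self.divergence_temp, below, mid)
        return out if out.ndim else float(out)

    def scaled(self, factor: float) -> "MO2Curve":
        return replace(self, base10=self.base10 * factor, peak=self.peak * factor)


@dataclass(frozen=True)
class HRCurve:
    """Heart rate (beats min⁻¹) versus temperature: Q10 rise with a high-
    temperature plateau (chronotropic ceiling near CTmax)."""

    base10: float
    q10: float
    plateau_temp: float

    def __call__(self, temp_c):
        t = np.minimum(np.asarray(temp_c, dtype=float), self.plateau_temp)
        out = self.base10 * self.q10 ** ((t - 10.0) / 10.0)
        return out if out.ndim else float(out)

    @classmethod
    def from_plateau(cls, base10: float, plateau_hr: float, plateau_temp: float) -> "HRCurve":
        """Build a curve hitting ``plateau_hr`` exactly at ``plateau_temp``."""
        q10 = (plateau_hr / base10) ** (10.0 / (plateau_temp - 10.0))
        return cls(base10=base10, q10=q10, plateau_temp=plateau_temp)

    def scaled(self, factor: float) -> "HRCurve":
        return replace(self, base10=self.base10 * factor)


@dataclass(frozen=True)
class BloodParams:
    """Venous blood panel baselines and near-CTmax kinetics.

    Lactate follows baseline + amp·(exp(rate·(T−onset)) − 1) above the onset
    temperature; PvO2 and [Hb] are linear in temperature; Hct interpolates
    anchor points (it rises with thermal stress, less so under hyperoxia).
    """

    pvo2_base10_kpa: float
    pvo2_slope_kpa_per_c: float
    hct_anchors: tuple[tuple[float, float], ...]
    hb_base10_g_dl: float
    hb_slope_g_dl_per_c: float
    lactate_baseline_mm: float
    lactate_onset_c: float
    lactate_amp_mm: float
    lactate_rate_per_c: float

    def pvo2(self, temp_c: float) -> float:
        return self.pvo2_base10_kpa + self.pvo2_slope_kpa_per_c * (temp_c - 10.0)

    def hct(self, temp_c: float) -> float:
        xs = [a[0] for a in self.hct_anchors]
        ys = [a[1] for a in self.hct_anchors]
        return float(np.interp(temp_c, xs, ys))

    def hb(self, temp_c: float) -> float:
        return self.hb_base10_g_dl + self.hb_slope_g_dl_per_c * (temp_c - 10.0)

    def lactate(self, temp_c: float) -> float:
        if temp_c <= self.lactate_onset_c:
            return self.lactate_baseline_mm
        return self.lactate_baseline_mm + self.lactate_amp_mm * (
            math.exp(self.lactate_rate_per_c * (temp_c - self.lactate_onset_c)) - 1.0
        )


@dataclass(frozen=True)
class CTmaxDist:
    """Loss-of-equilibrium temperature: normal(mean, sd) truncated to (lower, upper)."""

    mean: float
    sd: float
    lower: float = 20.0
    upper: float = 30.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("CTmax sd must be >= 0")
        if not self.lower < self.mean < self.upper:
            raise ConfigurationError("CTmax mean must lie inside the truncation bounds")


@dataclass(frozen=True)
class BackgroundParams:
    """Non-fish chamber O2 slope (mg O2 L⁻¹ min⁻¹) at the protocol start
    temperature and at the CTmax temperature; linear in between."""

    slope_at_start: float = 0.02
    slope_at_end: float = -0.01


@dataclass(frozen=True)
class FishPhenotype:
    """Ground-truth physiology of one fish (or a treatment template)."""

    mass: float  # kg
    mo2_curve: MO2Curve
    hr_curve: HRCurve
    sv_level: float  # ml beat^-1 kg^-1
    ctmax_dist: CTmaxDist
    blood_params: BloodParams
    background: BackgroundParams = BackgroundParams()

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ConfigurationError("mass must be positive")
        if self.sv_level <= 0:
            raise ConfigurationError("sv_level must be positive")

    def cardiac_output(self, temp_c):
        """True mass-specific cardiac output, ml min⁻¹ kg⁻¹."""
        return self.hr_curve(temp_c) * self.sv_level


# ---------------------------------------------------------------------------
# Treatment calibration
# ---------------------------------------------------------------------------

# Group-level calibration constants. MO2 plateaus, the CO/SV contrast at the
# maximal-MO2 window and the CTmax separation are the recovery targets of the
# downstream pipeline.
_NORMOXIA_MAX_CO = 62.4  # ml min^-1 kg^-1 at the maximal-MO2 window
_CO_CONTRAST = 1.33  # hyperoxia / normoxia cardiac output
_SV_CONTRAST = 1.46  # hyperoxia / normoxia stroke volume
_NORMOXIA_SV = 0.60  # ml beat^-1 kg^-1


def default_phenotype(group: str) -> FishPhenotype:
    """Treatment-template phenotype for ``"normoxia"`` or ``"hyperoxia"``."""
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "normoxia":
        sv = _NORMOXIA_SV
        hr_plateau = _NORMOXIA_MAX_CO / sv  # 104 bpm
        return FishPhenotype(
            mass=0.9,
            mo2_curve=MO2Curve(base10=85.0, q10=2.35, divergence_temp=23.0,
                               peak=292.8, peak_temp=24.5),
            hr_curve=HRCurve.from_plateau(55.0, hr_plateau, 24.5),
            sv_level=sv,
            ctmax_dist=CTmaxDist(mean=26.0, sd=0.25),
            blood_params=BloodParams(
                pvo2_base10_kpa=4.2,
                pvo2_slope_kpa_per_c=-0.1375,
                hct_anchors=((10.0, 27.0), (24.0, 32.0), (26.0, 37.0)),
                hb_base10_g_dl=9.0,
                hb_slope_g_dl_per_c=0.05,
                lactate_baseline_mm=0.7,
                lactate_onset_c=23.5,
                lactate_amp_mm=0.4,
                lactate_rate_per_c=1.0,
            ),
        )
    sv = _NORMOXIA_SV * _SV_CONTRAST
    hr_plateau = _NORMOXIA_MAX_CO * _CO_CONTRAST / sv  # ≈94.7 bpm
    return FishPhenotype(
        mass=0.9,
        mo2_curve=MO2Curve(base10=85.0, q10=2.35, divergence_temp=23.0,
                           peak=462.1, peak_temp=25.0),
        hr_curve=HRCurve.from_plateau(55.0, hr_plateau, 25.0),
        sv_level=sv,
        ctmax_dist=CTmaxDist(mean=26.87, sd=0.25),
        blood_params=BloodParams(
            pvo2_base10_kpa=5.8,
            pvo2_slope_kpa_per_c=-0.1625,
            hct_anchors=((10.0, 22.0), (24.0, 25.0), (26.0, 29.0)),
            hb_base10_g_dl=7.6,
            hb_slope_g_dl_per_c=0.05,
            lactate_baseline_mm=0.7,
            lactate_onset_c=25.2,
            lactate_amp_mm=0.4,
            lactate_rate_per_c=1.0,
        ),
    )


@dataclass(frozen=True)
class PopulationVariation:
    """Inter-individual scatter applied to a treatment template.

    Multiplicative log-normal factors (unit mean) scale the MO2 curve, the
    stroke volume and the heart-rate curve; HR and SV deviations are
    negatively correlated because cardiac output, not its factors, is the
    regulated quantity. Body mass is a truncated normal.
    """

    mo2_cv: float = 0.06
    sv_cv: float = 0.04
    hr_cv: float = 0.03
    hr_sv_corr: float = -0.6
    mass_mean_kg: float = 0.9
    mass_sd_kg: float = 0.14
    mass_bounds_kg: tuple[float, float] = (0.4, 1.6)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def sample_phenotype(
    template: FishPhenotype,
    rng: np.random.Generator,
    variation: PopulationVariation = PopulationVariation(),
) -> FishPhenotype:
    """Draw one individual phenotype around a treatment template."""
    s_mo2 = _lognormal_sigma(variation.mo2_cv)
    f_mo2 = math.exp(rng.normal(-0.5 * s_mo2**2, s_mo2)) if s_mo2 > 0 else 1.0

    s_hr = _lognormal_sigma(variation.hr_cv)
    s_sv = _lognormal_sigma(variation.sv_cv)
    rho = variation.hr_sv_corr
    z1, z2 = rng.standard_normal(2)
    l_hr = s_hr * z1 - 0.5 * s_hr**2
    l_sv = s_sv * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2) - 0.5 * s_sv**2
    f_hr, f_sv = math.exp(l_hr), math.exp(l_sv)

    lo, hi = variation.mass_bounds_kg
    if variation.mass_sd_kg == 0:
        mass = variation.mass_mean_kg
    else:
        mass = float(
            truncnorm.rvs(
                (lo - variation.mass_mean_kg) / variation.mass_sd_kg,
                (hi - variation.mass_mean_kg) / variation.mass_sd_kg,
                loc=variation.mass_mean_kg,
                scale=variation.mass_sd_kg,
                random_state=rng,
            )
        )
    return replace(
        template,
        mass=mass,
        mo2_curve=template.mo2_curve.scaled(f_mo2),
        hr_curve=template.hr_curve.scaled(f_hr),
        sv_level=template.sv_level * f_sv,
    )


def draw_ctmax(fish: FishPhenotype, rng: np.random.Generator) -> float:
    """Loss-of-equilibrium temperature from the fish's truncated-normal CTmax law."""
    d = fish.ctmax_dist
    if d.sd == 0:
        return d.mean
    a = (d.lower - d.mean) / d.sd
    b = (d.upper - d.mean) / d.sd
    return float(truncnorm.rvs(a, b, loc=d.mean, scale=d.sd, random_state=rng))


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------


def _background_line(bg: BackgroundParams, temp_start: float, temp_end: float):
    """Linear background slope model anchored at the start and end temperatures."""
    def line(temp):
        frac = (np.asarray(temp, dtype=float) - temp_start) / (temp_end - temp_start)
        return bg.slope_at_start + (bg.slope_at_end - bg.slope_at_start) * frac
    return line


def _grid_index(time_s: float, dt: float, n: int) -> int:
    return min(int(round(time_s / dt)), n - 1)


def _completed_cycles(protocol: RampProtocol, t_end: float):
    return [c for c in protocol.measurement_cycles() if c.closed_end_s <= t_end + 1e-9]


def generate_o2_trace(
    fish: FishPhenotype,
    protocol: RampProtocol,
    o2_level_pct: float,
    respirometer_volume_l: float = 10.0,
    rng: np.random.Generator | None = None,
    *,
    ctmax_temp: float | None = None,
    noise_sd_pct: float = 0.08,
    dt: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Simulate the water-O2 channel of one trial.

    During each closed phase the O2 concentration declines linearly at the
    fish rate ``MO2(T)·mass/(V−V_fish)`` plus the temperature-dependent
    background slope; between closed phases the chamber relaxes
    exponentially back to the treatment set-point. Returns
    ``(trace, events, cycle_truth)`` where the trace has columns ``time_s``,
    ``temp_C``, ``o2_airsat_pct``.
    """
    v_fish = fish.mass / 1.0  # fish density 1.0 kg L^-1
    v_eff = respirometer_volume_l - v_fish
    if v_eff <= 0:
        raise ConfigurationError("respirometer volume must exceed fish volume")
    if o2_level_pct <= 0:
        raise ConfigurationError("O2 set-point must be positive")
    rng = np.random.default_rng() if rng is None else rng

    times, temps = generate_temperature_profile(protocol, dt)
    if ctmax_temp is not None:
        idx = int(np.searchsorted(temps, ctmax_temp, side="left"))
        if idx < len(times):
            times, temps = times[: idx + 1], temps[: idx + 1]
    n = len(times)
    t_end = times[-1]
    bg_temp_end = ctmax_temp if (ctmax_temp is not None and temps[-1] >= ctmax_temp) else temps[-1]
    bg = _background_line(fish.background, protocol.start_temp, bg_temp_end)

    airsat = np.empty(n)
    cycles = _completed_cycles(protocol, t_end)
    cycle_truth: list[dict] = []
    events: list[tuple[float, str]] = []

    prev_idx = 0
    prev_val = o2_level_pct
    t_ref = times[0]

    def fill_open(i0: int, i1: int, t_ref: float, v_ref: float) -> None:
        """Exponential relaxation toward the set-point over [i0, i1)."""
        if i1 <= i0:
            return
        seg = slice(i0, i1)
        airsat[seg] = o2_level_pct + (v_ref - o2_level_pct) * np.exp(
            -(times[seg] - t_ref) / FLUSH_TAU_S
        )

    for cyc in cycles:
        i0 = _grid_index(cyc.closed_start_s, dt, n)
        i1 = _grid_index(cyc.closed_end_s, dt, n)
        fill_open(prev_idx, i0, t_ref, prev_val)
        start_val = o2_level_pct + (prev_val - o2_level_pct) * math.exp(
            -(times[i0] - t_ref) / FLUSH_TAU_S
        )
        temp = cyc.step_temp
        sat = o2_saturation_mgL(temp)
        fish_slope = -(fish.mo2_curve(temp) * fish.mass) / v_eff / 60.0  # mg/L/min
        bg_slope = float(bg(temp))
        total = fish_slope + bg_slope
        conc = start_val / 100.0 * sat + total * (times[i0 : i1 + 1] - times[i0]) / 60.0
        if conc.min() <= 0.0:
            raise SimulationError(
                "chamber O2 driven to zero during a closed phase "
                "(fish too large or closed phase too long)"
            )
        airsat[i0 : i1 + 1] = conc / sat * 100.0
        prev_idx = i1 + 1
        prev_val = airsat[i1]
        t_ref = times[i1]
        events.append((times[i0], "closed_start"))
        events.append((times[i1], "closed_end"))
        if cyc.flush_end_s <= t_end + 1e-9:
            events.append((cyc.flush_start_s, "flush_start"))
            events.append((cyc.flush_end_s, "flush_end"))
        cycle_truth.append(
            {
                "step_temp": temp,
                "index": cyc.index,
                "closed_start_s": times[i0],
                "closed_end_s": times[i1],
                "fish_slope_mgL_min": fish_slope,
                "bg_slope_mgL_min": bg_slope,
                "mo2_true": float(fish.mo2_curve(temp)),
            }
        )
    fill_open(prev_idx, n, t_ref, prev_val)

    if noise_sd_pct > 0:
        airsat = airsat + rng.normal(0.0, noise_sd_pct, n)

    trace = pd.DataFrame({"time_s": times, "temp_C": temps, "o2_airsat_pct": airsat})
    ev = pd.DataFrame(sorted(events), columns=["time_s", "event"])
    return trace, ev, cycle_truth


def generate_flow_trace(
    fish: FishPhenotype,
    protocol: RampProtocol,
    rng: np.random.Generator | None = None,
    *,
    ctmax_temp: float | None = None,
    noise_frac: float = 0.05,
    dt: float = 0.1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate the pulsatile ventral-aortic flow channel (ml min⁻¹, absolute).

    Each beat is a half-rectified sinusoid over a small diastolic baseline;
    the instantaneous beat frequency follows the fish's HR(T) curve and the
    waveform amplitude is set so the time-mean flow equals HR·SV·mass. Returns
    ``(trace, beat_times)`` with ground-truth systolic peak times.
    """
    rng = np.random.default_rng() if rng is None else rng
    times, temps = generate_temperature_profile(protocol, dt)
    if ctmax_temp is not None:
        idx = int(np.searchsorted(temps, ctmax_temp, side="left"))
        if idx < len(times):
            times, temps = times[: idx + 1], temps[: idx + 1]

    hr = np.asarray(fish.hr_curve(temps), dtype=float)
    if np.any(hr <= 0):
        raise ConfigurationError("heart-rate curve must be positive over the protocol")
    fs = 1.0 / dt
    if hr.max() / 60.0 > fs / MIN_SAMPLES_PER_BEAT:
        raise ConfigurationError(
            f"heart rate {hr.max():.0f} bpm not resolvable at {fs:.0f} Hz sampling"
        )

    phase = np.cumsum(hr / 60.0 * dt)  # cumulative beats
    mean_target = hr * fish.sv_level * fish.mass  # ml min^-1 absolute
    baseline = 0.1 * mean_target
    amp = 0.9 * math.pi * mean_target
    flow = baseline + amp * np.maximum(0.0, np.sin(2.0 * math.pi * phase))

    # True systolic peaks sit at phase = m + 1/4.
    m0 = math.ceil(phase[0] - 0.25)
    m1 = math.floor(phase[-1] - 0.25)
    beat_times = (
        np.interp(np.arange(m0, m1 + 1) + 0.25, phase, times)
        if m1 >= m0
        else np.empty(0)
    )

    if noise_frac > 0:
        flow = flow + rng.normal(0.0, noise_frac * float(amp.mean()), len(flow))

    trace = pd.DataFrame({"time_s": times, "flow_mL_min": flow})
    return trace, beat_times


def generate_blood_samples(
    fish: FishPhenotype,
    protocol: RampProtocol,
    rng: np.random.Generator | None = None,
    *,
    ctmax_temp: float | None = None,
    ctmax_time_s: float | None = None,
    noise_cv: float = 0.05,
) -> pd.DataFrame:
    """Venous blood panels at the protocol sampling temperatures plus at CTmax."""
    rng = np.random.default_rng() if rng is None else rng
    steps = np.asarray(protocol.step_temps)

    rows = []
    for temp, t_s in protocol.blood_sample_times():
        if ctmax_time_s is not None and t_s > ctmax_time_s:
            continue
        rows.append((t_s, temp, temp, False))
    if ctmax_temp is not None and ctmax_time_s is not None:
        nearest = float(steps[np.argmin(np.abs(steps - ctmax_temp))])
        rows.append((ctmax_time_s, nearest, ctmax_temp, True))

    s = _lognormal_sigma(noise_cv) if noise_cv > 0 else 0.0

    def jitter(v: float) -> float:
        if s == 0:
            return v
        return v * math.exp(rng.normal(-0.5 * s * s, s))

    bp = fish.blood_params
    recs = []
    for t_s, step, temp, at_ct in rows:
        recs.append(
            {
                "time_s": t_s,
                "step_temp": step,
                "temp_C": temp,
                "at_ctmax": at_ct,
                "pvo2_kPa": jitter(bp.pvo2(temp)),
                "hct_pct": jitter(bp.hct(temp)),
                "hb_g_dL": jitter(bp.hb(temp)),
                "lactate_mM": jitter(bp.lactate(temp)),
            }
        )
    return pd.DataFrame.from_records(
        recs,
        columns=[
            "time_s", "step_temp", "temp_C", "at_ctmax",
            "pvo2_kPa", "hct_pct", "hb_g_dL", "lactate_mM",
        ],
    )


# ---------------------------------------------------------------------------
# Whole trials and cohorts
# ---------------------------------------------------------------------------


@dataclass
class FishTrial:
    """One synthetic fish: raw channels, event log, blood panel and truth."""

    fish_id: str
    group: str
    trace: pd.DataFrame  # time_s, temp_C, o2_airsat_pct, flow_mL_min
    events: pd.DataFrame  # time_s, event
    blood: pd.DataFrame
    truth: dict
    beat_times: np.ndarray


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a two-arm synthetic trial set."""

    n_per_group: int = 9
    seed: int = 42
    o2_levels: tuple[float, float] = (96.9, 208.8)  # % air sat: normoxia, hyperoxia
    o2_noise_sd_pct: float = 0.08
    flow_noise_frac: float = 0.05
    blood_noise_cv: float = 0.05
    respirometer_volume_l: float = 10.0
    dt: float = 0.1
    variation: PopulationVariation = PopulationVariation()
    protocol: RampProtocol = field(default_factory=default_protocol)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if any(level <= 0 for level in self.o2_levels):
            raise ConfigurationError("o2_levels must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")


@dataclass
class Cohort:
    config: CohortConfig
    trials: list[FishTrial]

    def group(self, name: str) -> list[FishTrial]:
        return [t for t in self.trials if t.group == name]


def _fish_rng(seed: int, group_idx: int, fish_idx: int) -> np.random.Generator:
    """Independent, reproducible substream per fish from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, fish_idx))
    )


def generate_fish_trial(
    fish_id: str,
    group: str,
    phenotype: FishPhenotype,
    config: CohortConfig,
    rng: np.random.Generator,
) -> FishTrial:
    """Assemble one complete trial (traces, events, blood, truth) for a fish."""
    o2_level = config.o2_levels[GROUPS.index(group)]
    protocol = config.protocol
    ctmax = draw_ctmax(phenotype, rng)

    _, full_temps = generate_temperature_profile(protocol, config.dt)
    ctmax_reached = bool(full_temps[-1] >= ctmax)

    o2_trace, events, cycle_truth = generate_o2_trace(
        phenotype, protocol, o2_level, config.respirometer_volume_l, rng,
        ctmax_temp=ctmax if ctmax_reached else None,
        noise_sd_pct=config.o2_noise_sd_pct, dt=config.dt,
    )
    flow_trace, beat_times = generate_flow_trace(
        phenotype, protocol, rng,
        ctmax_temp=ctmax if ctmax_reached else None,
        noise_frac=config.flow_noise_frac, dt=config.dt,
    )
    trace = o2_trace.assign(flow_mL_min=flow_trace["flow_mL_min"].to_numpy())
    t_end = float(trace["time_s"].iloc[-1])

    event_rows = [(float(t), str(e)) for t, e in events.itertuples(index=False)]
    blood = generate_blood_samples(
        phenotype, protocol, rng,
        ctmax_temp=ctmax if ctmax_reached else None,
        ctmax_time_s=t_end if ctmax_reached else None,
        noise_cv=config.blood_noise_cv,
    )
    for t_s in blood.loc[~blood["at_ctmax"], "time_s"]:
        event_rows.append((float(t_s), "blood_sample"))
    if ctmax_reached:
        event_rows.append((t_end, "blood_sample"))
        event_rows.append((t_end, "loss_of_equilibrium"))
    events = pd.DataFrame(
        sorted(event_rows, key=lambda r: (r[0], r[1])), columns=["time_s", "event"]
    )

    # Per-step truth for fully completed plateaus.
    by_step: dict[float, int] = {}
    for c in cycle_truth:
        by_step[c["step_temp"]] = by_step.get(c["step_temp"], 0) + 1
    steps_truth = []
    for step, count in sorted(by_step.items()):
        if count == protocol.cycles_per_plateau:
            hr = float(phenotype.hr_curve(step))
            sv = phenotype.sv_level
            steps_truth.append(
                {"step_temp": step, "mo2": float(phenotype.mo2_curve(step)),
                 "hr": hr, "sv": sv, "co": hr * sv}
            )

    bg_temp_end = ctmax if ctmax_reached else float(full_temps[-1])
    truth = {
        "fish_id": fish_id,
        "group": group,
        "mass_kg": phenotype.mass,
        "ctmax_c": ctmax,
        "ctmax_reached": ctmax_reached,
        "sv_ml_beat_kg": phenotype.sv_level,
        "o2_level_pct": o2_level,
        "respirometer_volume_l": config.respirometer_volume_l,
        "background": {
            "temp_start": protocol.start_temp,
            "slope_at_start": phenotype.background.slope_at_start,
            "temp_end": bg_temp_end,
            "slope_at_end": phenotype.background.slope_at_end,
        },
        "steps": steps_truth,
        "cycles": cycle_truth,
    }
    return FishTrial(
        fish_id=fish_id, group=group, trace=trace, events=events,
        blood=blood, truth=truth, beat_times=beat_times,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the two-arm cohort; fully determined by ``config.seed``."""
    trials: list[FishTrial] = []
    for g_idx, group in enumerate(GROUPS):
        template = default_phenotype(group)
        for i in range(config.n_per_group):
            rng = _fish_rng(config.seed, g_idx, i)
            phenotype = sample_phenotype(template, rng, config.variation)
            fish_id = f"{group[:3]}_{i + 1:02d}"
            trials.append(generate_fish_trial(fish_id, group, phenotype, config, rng))
    cohort = Cohort(config=config, trials=trials)
    if config.output_dir is not None:
        write_cohort(cohort, config.output_dir)
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Persist a cohort: per-fish trace/events/blood CSVs and truth JSON."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    cfg = asdict(cohort.config)
    cfg["protocol"] = asdict(cohort.config.protocol)
    with open(root / "cohort_config.json", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
    for trial in cohort.trials:
        d = root / trial.fish_id
        d.mkdir(exist_ok=True)
        trial.trace.to_csv(d / "trace.csv", index=False, float_format="%.5f")
        trial.events.to_csv(d / "events.csv", index=False, float_format="%.1f")
        trial.blood.to_csv(d / "blood.csv", index=False, float_format="%.5f")
        with open(d / "truth.json", "w") as fh:
            json.dump(trial.truth, fh, indent=1, sort_keys=True)
    return root
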