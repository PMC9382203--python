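import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from thermoramp.errors import ConfigurationError, SimulationError
from thermoramp.protocol import generate_temperature_profile
from thermoramp.synthgen import (
    CTmaxDist,
    CohortConfig,
    HRCurve,
    MO2Curve,
    default_phenotype,
    draw_ctmax,
    generate_blood_samples,
    generate_cohort,
    generate_flow_trace,
    generate_o2_trace,
    write_cohort,
)
from thermoramp.units import airsat_to_mgL

from conftest import make_small_protocol, zero_noise_config

from dataclasses import replace


def flat_hr_phenotype(hr_bpm=60.0, sv=0.5):
    """Phenotype with temperature-independent heart rate for clean pulse tests."""
    ph = default_phenotype("normoxia")
    return replace(ph, hr_curve=HRCurve(base10=hr_bpm, q10=1.0, plateau_temp=40.0), sv_level=sv)


class TestO2Trace:
    def test_zero_noise_closed_slope_is_conserved(self):
        # With no noise and a known background, every closed-phase slope in
        # the trace equals -MO2·mass/(V−V_fish) + bg exactly (conservation).
        ph = default_phenotype("normoxia")
        proto = make_small_protocol()
        trace, events, cycles = generate_o2_trace(
            ph, proto, 96.9, 10.0, np.random.default_rng(0), noise_sd_pct=0.0
        )
        assert len(cycles) == 2 * len(proto.step_temps)
        t = trace["time_s"].to_numpy()
        for cyc in cycles:
            mask = (t >= cyc["closed_start_s"]) & (t <= cyc["closed_end_s"])
            sub = trace.loc[mask]
            conc = airsat_to_mgL(sub["o2_airsat_pct"].to_numpy(), sub["temp_C"].to_numpy())
            slope = np.polyfit((sub["time_s"] - sub["time_s"].iloc[0]) / 60.0, conc, 1)[0]
            v_eff = 10.0 - ph.mass
            expected = -cyc["mo2_true"] * ph.mass / v_eff / 60.0 + cyc["bg_slope_mgL_min"]
            assert slope == pytest.approx(expected, rel=1e-9)
            assert cyc["fish_slope_mgL_min"] + cyc["bg_slope_mgL_min"] == pytest.approx(
                expected, rel=1e-12
            )

    def test_positive_background_with_idle_fish_raises_o2(self):
        ph = default_phenotype("normoxia")
        ph = replace(
            ph, mo2_curve=MO2Curve(base10=1e-9, q10=1.0, divergence_temp=23.0,
                                   peak=1e-9, peak_temp=24.5)
        )
        proto = make_small_protocol()
        trace, _, cycles = generate_o2_trace(
            ph, proto, 100.0, 10.0, np.random.default_rng(0), noise_sd_pct=0.0
        )
        first = cycles[0]  # at 10°C the background anchor is positive
        t = trace["time_s"].to_numpy()
        mask = (t >= first["closed_start_s"]) & (t <= first["closed_end_s"])
        o2 = trace.loc[mask, "o2_airsat_pct"].to_numpy()
        assert first["bg_slope_mgL_min"] > 0
        assert o2[-1] > o2[0]

    def test_noisy_slope_recovers_truth_within_ols_error(self):
        # OLS refit of a seeded noisy segment lands within 2 sd of the
        # closed-form OLS slope standard error.
        ph = default_phenotype("normoxia")
        proto = make_small_protocol()
        trace, _, cycles = generate_o2_trace(
            ph, proto, 96.9, 10.0, np.random.default_rng(7), noise_sd_pct=0.08
        )
        t = trace["time_s"].to_numpy()
        cyc = cycles[-1]
        mask = (t >= cyc["closed_start_s"]) & (t <= cyc["closed_end_s"])
        sub = trace.loc[mask]
        x = (sub["time_s"].to_numpy() - sub["time_s"].iloc[0]) / 60.0
        y = np.asarray(airsat_to_mgL(sub["o2_airsat_pct"].to_numpy(), sub["temp_C"].to_numpy()))
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        se = np.sqrt(resid.var(ddof=2) / np.sum((x - x.mean()) ** 2))
        truth = cyc["fish_slope_mgL_min"] + cyc["bg_slope_mgL_min"]
        assert abs(slope - truth) < 2.0 * se

    def test_oversized_fish_drains_chamber(self):
        ph = replace(default_phenotype("normoxia"), mass=0.95)
        with pytest.raises(SimulationError):
            generate_o2_trace(
                ph, make_small_protocol(), 96.9, 1.0,
                np.random.default_rng(0), noise_sd_pct=0.0,
            )

    def test_volume_must_exceed_fish_volume(self):
        ph = default_phenotype("normoxia")
        with pytest.raises(ConfigurationError):
            generate_o2_trace(ph, make_small_protocol(), 96.9, 0.5, np.random.default_rng(0))


class TestFlowTrace:
    def test_clean_60bpm_train_has_60_peaks_per_minute(self):
        ph = flat_hr_phenotype(60.0)
        proto = make_small_protocol()
        _, beats = generate_flow_trace(ph, proto, noise_frac=0.0)
        in_minute = beats[(beats >= 100.0) & (beats < 160.0)]
        assert abs(len(in_minute) - 60) <= 1

    def test_window_mean_flow_matches_hr_times_sv(self):
        # Continuous-time mean of the pulse train is HR·SV·mass; discrete
        # 10 Hz sampling over a closed window stays within 0.5%.
        ph = default_phenotype("hyperoxia")
        proto = make_small_protocol()
        trace, _ = generate_flow_trace(ph, proto, noise_frac=0.0)
        t = trace["time_s"].to_numpy()
        for cyc in proto.measurement_cycles():
            mask = (t >= cyc.closed_start_s) & (t <= cyc.closed_end_s)
            mean_flow = trace.loc[mask, "flow_mL_min"].mean()
            expected = ph.hr_curve(cyc.step_temp) * ph.sv_level * ph.mass
            assert mean_flow == pytest.approx(expected, rel=5e-3)

    def test_sv_doubling_doubles_window_mean(self):
        ph = flat_hr_phenotype(60.0, sv=0.4)
        ph2 = replace(ph, sv_level=0.8)
        proto = make_small_protocol()
        m1 = generate_flow_trace(ph, proto, noise_frac=0.0)[0]["flow_mL_min"].mean()
        m2 = generate_flow_trace(ph2, proto, noise_frac=0.0)[0]["flow_mL_min"].mean()
        assert m2 == pytest.approx(2.0 * m1, rel=1e-6)

    def test_integrated_flow_per_beat_recovers_stroke_volume(self):
        ph = flat_hr_phenotype(72.0, sv=0.5)
        proto = make_small_protocol()
        trace, beats = generate_flow_trace(
            ph, proto, np.random.default_rng(2), noise_frac=0.05
        )
        t = trace["time_s"].to_numpy()
        mask = (t >= 60.0) & (t <= 360.0)
        volume_ml = trace.loc[mask, "flow_mL_min"].mean() * (300.0 / 60.0)
        n_beats = np.sum((beats >= 60.0) & (beats <= 360.0))
        sv_abs = volume_ml / n_beats  # ml per beat, absolute
        assert sv_abs == pytest.approx(ph.sv_level * ph.mass, rel=0.03)

    def test_unresolvable_heart_rate_rejected(self):
        ph = flat_hr_phenotype(200.0)
        with pytest.raises(ConfigurationError):
            generate_flow_trace(ph, make_small_protocol(), noise_frac=0.0)


class TestCTmax:
    def test_zero_sd_returns_mean_exactly(self):
        ph = replace(default_phenotype("normoxia"), ctmax_dist=CTmaxDist(25.0, 0.0))
        assert draw_ctmax(ph, np.random.default_rng(0)) == 25.0

    def test_same_seed_same_draw(self):
        ph = default_phenotype("hyperoxia")
        a = draw_ctmax(ph, np.random.default_rng(11))
        b = draw_ctmax(ph, np.random.default_rng(11))
        assert a == b

    def test_draws_truncated_and_unbiased(self):
        ph = default_phenotype("normoxia")
        rng = np.random.default_rng(4)
        draws = np.array([draw_ctmax(ph, rng) for _ in range(10_000)])
        assert np.all((draws > 20.0) & (draws < 30.0))
        se = ph.ctmax_dist.sd / np.sqrt(len(draws))
        assert abs(draws.mean() - ph.ctmax_dist.mean) < 3.0 * se


class TestBloodSamples:
    def test_equal_parameters_equal_panels_without_noise(self):
        proto = make_small_protocol()
        ph = default_phenotype("normoxia")
        a = generate_blood_samples(ph, proto, noise_cv=0.0)
        b = generate_blood_samples(ph, proto, noise_cv=0.0)
        pd.testing.assert_frame_equal(a, b)
        assert (a[["pvo2_kPa", "hct_pct", "hb_g_dL", "lactate_mM"]] > 0).all().all()

    def test_lactate_flat_when_onset_beyond_ctmax(self):
        ph = default_phenotype("normoxia")
        bp = replace(ph.blood_params, lactate_onset_c=29.0)
        ph = replace(ph, blood_params=bp)
        panel = generate_blood_samples(
            ph, make_small_protocol(), noise_cv=0.0, ctmax_temp=20.0, ctmax_time_s=3000.0
        )
        assert np.allclose(panel["lactate_mM"], bp.lactate_baseline_mm)

    def test_pvo2_treatment_offset_at_26C_matches_configuration(self):
        n = default_phenotype("normoxia").blood_params
        h = default_phenotype("hyperoxia").blood_params
        assert h.pvo2(26.0) - n.pvo2(26.0) == pytest.approx(1.2, abs=1e-9)
        # Hct runs lower under hyperoxia at every sampling temperature.
        for temp in (10.0, 20.0, 24.0, 26.0):
            assert h.hct(temp) < n.hct(temp)


class TestCohort:
    def test_cohort_is_byte_identical_under_same_seed(self, tmp_path):
        cfg = CohortConfig(n_per_group=1, seed=9, protocol=make_small_protocol())
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(cfg), d1)
        write_cohort(generate_cohort(cfg), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_n_per_group_one_yields_two_fish(self):
        cohort = generate_cohort(zero_noise_config())
        assert len(cohort.trials) == 2
        assert {t.group for t in cohort.trials} == {"normoxia", "hyperoxia"}

    def test_sidecar_matches_regenerated_truth(self, tmp_path):
        cfg = CohortConfig(n_per_group=1, seed=13, protocol=make_small_protocol())
        root = write_cohort(generate_cohort(cfg), tmp_path / "c")
        regenerated = generate_cohort(cfg)
        for trial in regenerated.trials:
            with open(root / trial.fish_id / "truth.json") as fh:
                on_disk = json.load(fh)
            assert on_disk == json.loads(json.dumps(trial.truth))

    def test_trace_columns_and_event_vocabulary(self, tiny_cohort):
        trial = tiny_cohort.trials[0]
        assert list(trial.trace.columns) == ["time_s", "temp_C", "o2_airsat_pct", "flow_mL_min"]
        allowed = {"closed_start", "closed_end", "flush_start", "flush_end",
                   "blood_sample", "loss_of_equilibrium"}
        assert set(trial.events["event"]) <= allowed
        assert trial.trace["time_s"].is_monotonic_increasing
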