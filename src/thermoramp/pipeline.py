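"""Orchestrate simulate → respirometry → cardio → stats → meta into one run.

``run_all`` executes the stages on an in-memory synthetic cohort, writes each
stage's tabular outputs under ``<output_root>/<stage>/`` and a final report
(JSON + markdown rendered from the same dict, so every number in the
markdown is machine-readable). The whole run is a pure function of the
configuration, seed included.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardio as cardio_mod
from . import respirometry as resp_mod
from . import stats as stats_mod
from . import tolerance_meta as meta_mod
from .respirometry import BackgroundModel
from .synthgen import Cohort, CohortConfig, FishTrial, generate_cohort, write_cohort

logger = logging.getLogger("thermoramp")

STAGES = ("simulate", "respirometry", "cardio", "stats", "meta")

#: Repeated-measures comparisons are restricted to steps at or below this
#: temperature (reached by every fish before loss of equilibrium).
ANOVA_MAX_TEMP = 25.0

#: Step used for the late-ramping blood comparison (pre-CTmax and at-CTmax
#: samples snapping to this step are pooled).
BLOOD_CONTRAST_STEP = 26.0

__all__ = ["RunConfig", "run_all", "write_report", "analyze_trial", "render_markdown"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    output_root: str = "thermoramp_run"
    stages: tuple[str, ...] = STAGES
    r2_min: float = resp_mod.DEFAULT_R2_MIN
    persist_traces: bool = False
    literature_table: str | None = None  # packaged table when None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cohort_keys = {f.name for f in dataclasses.fields(CohortConfig)}
        cohort_kwargs = {k: v for k, v in raw.items() if k in cohort_keys}
        if "o2_levels" in cohort_kwargs:
            cohort_kwargs["o2_levels"] = tuple(cohort_kwargs["o2_levels"])
        kwargs = {k: v for k, v in raw.items() if k in {
            "output_root", "stages", "r2_min", "persist_traces", "literature_table"
        }}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(cohort=CohortConfig(**cohort_kwargs), **kwargs)


def _stage_failure(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"stage '{stage}' failed: {exc}")


def analyze_trial(trial: FishTrial, r2_min: float = resp_mod.DEFAULT_R2_MIN) -> dict:
    """Respirometry + cardiac analysis of one fish, from its raw channels.

    Uses only what the lab would have: the trace, the event log and the
    trial metadata (mass, chamber volume, background anchor slopes). Returns
    per-fish outputs including the maximal-routine-MO2 window variables.
    """
    meta = trial.truth
    bg = BackgroundModel(**meta["background"])
    mass = meta["mass_kg"]
    volume = meta["respirometer_volume_l"]
    steps_present = sorted({c["step_temp"] for c in meta["cycles"]}) or [10.0]

    _, records_df, summary = resp_mod.process_fish(
        trial.trace, trial.events,
        fish_mass_kg=mass, respirometer_volume_l=volume,
        background=bg, step_temps=steps_present, r2_min=r2_min,
    )
    mo2_by_step = dict(zip(summary["step"], summary["mo2_rou"]))
    max_row = summary.loc[summary["is_max"]]
    max_step = float(max_row["step"].iloc[0]) if len(max_row) else None
    max_mo2 = float(max_row["mo2_rou"].iloc[0]) if len(max_row) else None

    segments = resp_mod.segment_cycles(trial.trace, trial.events, steps_present)
    intervals = [(s.step_temp, s.t0_s, s.t1_s) for s in segments]
    _, windows_df = cardio_mod.tie_windows(
        trial.trace, intervals, mo2_by_step, fish_mass_kg=mass, max_step=max_step,
    )

    loe = trial.events.loc[trial.events["event"] == "loss_of_equilibrium", "time_s"]
    if len(loe):
        t_loe = float(loe.iloc[0])
        temp = trial.trace["temp_C"].to_numpy()
        t = trial.trace["time_s"].to_numpy()
        ctmax_est = float(temp[np.searchsorted(t, t_loe, side="left").clip(0, len(t) - 1)])
    else:
        ctmax_est = None

    max_window = windows_df.loc[windows_df["is_max_window"]]
    out = {
        "fish_id": trial.fish_id,
        "group": trial.group,
        "mass_kg": mass,
        "records": records_df,
        "summary": summary,
        "windows": windows_df,
        "max_step": max_step,
        "max_mo2": max_mo2,
        "ctmax_est": ctmax_est,
    }
    for var in ("hr", "co", "sv", "avo2"):
        out[f"{var}_at_max"] = (
            float(max_window[var].iloc[0]) if len(max_window) else None
        )
    return out


def _blood_at_contrast_step(trial: FishTrial) -> pd.Series | None:
    """The fish's blood panel for the late-ramping contrast (see module docs)."""
    b = trial.blood
    rows = b.loc[b["step_temp"] == BLOOD_CONTRAST_STEP]
    if len(rows) == 0:
        return None
    regular = rows.loc[~rows["at_ctmax"]]
    return (regular.iloc[0] if len(regular) else rows.iloc[0])


def _group_summaries(per_fish: list[dict], cohort: Cohort) -> dict:
    groups: dict[str, dict] = {}
    for gname in ("normoxia", "hyperoxia"):
        rows = [f for f in per_fish if f["group"] == gname]
        ct = [f["ctmax_est"] for f in rows if f["ctmax_est"] is not None]
        d = {
            "n": len(rows),
            "mean_mass_kg": float(np.mean([f["mass_kg"] for f in rows])),
            "max_mo2_mean": float(np.mean([f["max_mo2"] for f in rows])),
            "max_mo2_sd": float(np.std([f["max_mo2"] for f in rows], ddof=1)),
            "max_mo2_temp_mean": float(np.mean([f["max_step"] for f in rows])),
            "ctmax_mean": float(np.mean(ct)) if ct else None,
            "ctmax_median": float(np.median(ct)) if ct else None,
            "n_ctmax_reached": len(ct),
        }
        for var in ("hr", "co", "sv", "avo2"):
            vals = [f[f"{var}_at_max"] for f in rows if f[f"{var}_at_max"] is not None]
            d[f"{var}_at_max_mean"] = float(np.mean(vals)) if vals else None
        groups[gname] = d
    return groups


def _contrasts(per_fish: list[dict], cohort: Cohort, groups: dict) -> dict:
    gn, gh = groups["normoxia"], groups["hyperoxia"]

    def vals(gname, key):
        return np.array(
            [f[key] for f in per_fish if f["group"] == gname and f[key] is not None]
        )

    out: dict = {
        "max_mo2_pct_diff": stats_mod.percent_difference(
            gn["max_mo2_mean"], gh["max_mo2_mean"]
        ),
    }
    for var in ("co", "sv", "hr", "avo2"):
        out[f"{var}_pct_diff"] = stats_mod.percent_difference(
            gn[f"{var}_at_max_mean"], gh[f"{var}_at_max_mean"]
        )
    # Group tests at the maximal-MO2 window (ln scale for size-like variables,
    # rank test for HR and CTmax).
    t, df, p = stats_mod.t_test_independent(
        stats_mod.ln_transform(vals("normoxia", "max_mo2")),
        stats_mod.ln_transform(vals("hyperoxia", "max_mo2")),
    )
    out["max_mo2_ttest_ln"] = {"t": t, "df": df, "p": p}
    u, p = stats_mod.mann_whitney(vals("normoxia", "hr_at_max"), vals("hyperoxia", "hr_at_max"))
    out["hr_mannwhitney"] = {"U": u, "p": p}

    ct_n = vals("normoxia", "ctmax_est")
    ct_h = vals("hyperoxia", "ctmax_est")
    if len(ct_n) >= 2 and len(ct_h) >= 2:
        out["ctmax"] = meta_mod.compare_ctmax(ct_n, ct_h)

    lac_n, lac_h = [], []
    for trial in cohort.trials:
        row = _blood_at_contrast_step(trial)
        if row is None:
            continue
        (lac_n if trial.group == "normoxia" else lac_h).append(float(row["lactate_mM"]))
    if len(lac_n) >= 2 and len(lac_h) >= 2:
        t, df, p = stats_mod.t_test_independent(lac_n, lac_h)
        out["lactate_contrast"] = {
            "step_c": BLOOD_CONTRAST_STEP,
            "normoxia_mean_mM": float(np.mean(lac_n)),
            "hyperoxia_mean_mM": float(np.mean(lac_h)),
            "n": [len(lac_n), len(lac_h)],
            "ttest": {"t": t, "df": df, "p": p},
        }
    return out


def _mo2_anova(per_fish: list[dict]) -> list[dict]:
    """Mixed two-way ANOVA of ln routine MO2 up to ``ANOVA_MAX_TEMP``."""
    rows = []
    for f in per_fish:
        for step, mo2 in zip(f["summary"]["step"], f["summary"]["mo2_rou"]):
            if step <= ANOVA_MAX_TEMP and mo2 > 0:
                rows.append(
                    {"subject": f["fish_id"], "group": f["group"],
                     "level": float(step), "value": float(np.log(mo2))}
                )
    long = pd.DataFrame(rows)
    results = stats_mod.mixed_anova(long)
    return [dataclasses.asdict(r) for r in results]


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs + report."""
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    report: dict = {
        "config": {
            "seed": config.cohort.seed,
            "n_per_group": config.cohort.n_per_group,
            "o2_levels_pct": list(config.cohort.o2_levels),
            "r2_min": config.r2_min,
        },
        "stages": {s: ("run" if s in enabled else "skipped") for s in STAGES},
    }

    cohort: Cohort | None = None
    per_fish: list[dict] | None = None

    t0 = time.perf_counter()
    if "simulate" in enabled:
        try:
            cohort = generate_cohort(config.cohort)
            if config.persist_traces:
                write_cohort(cohort, root / "simulate")
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise _stage_failure("simulate", exc) from exc
        logger.info("simulate: %d trials in %.1fs", len(cohort.trials), time.perf_counter() - t0)

    if "respirometry" in enabled or "cardio" in enabled:
        if cohort is None:
            report["stages"]["respirometry"] = report["stages"]["cardio"] = "skipped"
        else:
            t0 = time.perf_counter()
            try:
                per_fish = [analyze_trial(t, config.r2_min) for t in cohort.trials]
            except Exception as exc:  # noqa: BLE001
                raise _stage_failure("respirometry", exc) from exc
            logger.info("respirometry+cardio: %.1fs", time.perf_counter() - t0)
            if "respirometry" in enabled:
                d = root / "respirometry"
                d.mkdir(exist_ok=True)
                for f in per_fish:
                    f["records"].to_csv(d / f"{f['fish_id']}_mo2_records.csv", index=False)
                    f["summary"].to_csv(d / f"{f['fish_id']}_mo2_summary.csv", index=False)
            if "cardio" in enabled:
                d = root / "cardio"
                d.mkdir(exist_ok=True)
                for f in per_fish:
                    f["windows"].to_csv(d / f"{f['fish_id']}_cardio_windows.csv", index=False)

    if per_fish is not None and cohort is not None:
        groups = _group_summaries(per_fish, cohort)
        report["groups"] = groups
        if "stats" in enabled:
            try:
                report["contrasts"] = _contrasts(per_fish, cohort, groups)
                report["anova_mo2_rou_ln"] = _mo2_anova(per_fish)
            except Exception as exc:  # noqa: BLE001
                raise _stage_failure("stats", exc) from exc
            d = root / "stats"
            d.mkdir(exist_ok=True)
            pd.DataFrame(report["anova_mo2_rou_ln"]).to_csv(d / "anova.csv", index=False)
            pairwise = {
                k: v for k, v in report["contrasts"].items() if isinstance(v, dict)
            }
            with open(d / "pairwise.json", "w") as fh:
                json.dump(pairwise, fh, indent=1, sort_keys=True)

    if "meta" in enabled:
        try:
            entries = meta_mod.load_literature(config.literature_table)
            summaries = meta_mod.species_aggregate(entries)
            report["literature"] = meta_mod.prevalence_summary(summaries)
        except Exception as exc:  # noqa: BLE001
            raise _stage_failure("meta", exc) from exc
        d = root / "meta"
        d.mkdir(exist_ok=True)
        with open(d / "meta_summary.json", "w") as fh:
            json.dump(report["literature"], fh, indent=1, sort_keys=True)

    md, js = write_report(report)
    (root / "report.json").write_text(js)
    (root / "report.md").write_text(md)
    return report


def render_markdown(results: dict, _level: int = 0) -> str:
    """Render the report dict as markdown; every number comes from the dict."""
    lines: list[str] = []

    def emit(obj, indent: int, key: str | None = None):
        pad = "  " * indent
        if isinstance(obj, dict):
            if key is not None:
                lines.append(f"{pad}- **{key}**:")
            for k, v in obj.items():
                emit(v, indent + (0 if key is None else 1), k)
        elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], dict):
            lines.append(f"{pad}- **{key}**:")
            for i, v in enumerate(obj):
                emit(v, indent + 1, str(i))
        else:
            lines.append(f"{pad}- {key}: {json.dumps(obj)}")

    lines.append("# thermoramp run report")
    for k, v in results.items():
        lines.append(f"\n## {k}")
        emit(v, 0)
    return "\n".join(lines) + "\n"


def write_report(results: dict) -> tuple[str, str]:
    """(markdown, json) report pair; the markdown is rendered from the JSON."""
    if not results:
        raise ValueError("no stage results to report")
    js = json.dumps(results, indent=1, sort_keys=True, default=_json_default)
    md = render_markdown(json.loads(js))
    return md, js


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
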