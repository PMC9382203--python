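"""CTmax group comparison and the hyperoxia thermal-tolerance synthesis.

Two concerns live here. First, comparing loss-of-equilibrium temperatures
between O2 treatments for one trial (median and mean differences plus a
Mann–Whitney U test, since CTmax is typically non-normal). Second, a
packaged table of published hyperoxia-vs-normoxia upper-thermal-limit
comparisons across fishes, with per-species aggregation, prevalence
counting, and an LT50 sigmoidal-regression utility for studies that score
the fraction of unresponsive individuals rather than individual CTmax.

Counting rule for "increased tolerance": a species counts when any of its
conditions shows a statistically significant CTmax elevation, or — when no
condition was statistically tested at all — when its largest difference is
positive. The magnitude range is reported over statistically significant
species only, rounded to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import FitError
from .stats import mann_whitney

__all__ = [
    "LiteratureEntry",
    "SpeciesSummary",
    "LT50Fit",
    "packaged_table_path",
    "load_literature",
    "species_aggregate",
    "prevalence_summary",
    "compare_ctmax",
    "lt50_fit",
    "ci_separated",
]

SIGNIFICANCE_LEVELS = ("yes", "no", "na")


@dataclass(frozen=True)
class LiteratureEntry:
    """One published hyperoxia/normoxia thermal-limit comparison."""

    species: str
    ecotype: str
    climatic_region: str
    acclimation_temp_c: float
    heating_rate_c_per_h: float | None
    o2_level_pct_airsat: float | None  # None where the study did not state it
    ctmax_diff_c: float  # hyperoxia − normoxia
    significant: str  # yes / no / na (no statistical comparison available)
    reference: str


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_conditions: int
    max_diff: float
    any_significant: bool
    increased: bool


@dataclass(frozen=True)
class LT50Fit:
    """Two-parameter logistic fit of unresponsiveness against temperature."""

    lt50: float
    scale: float  # °C; smaller = steeper transition
    ci_low: float
    ci_high: float
    n_bootstrap: int


def packaged_table_path() -> Path:
    """Path of the packaged literature table CSV."""
    return Path(resources.files("thermoramp").joinpath("data/literature_table.csv"))


def load_literature(path: str | Path | None = None) -> list[LiteratureEntry]:
    """Load and validate the literature table; all violations are itemized."""
    path = packaged_table_path() if path is None else Path(path)
    df = pd.read_csv(path, dtype={"reference": str})
    required = [
        "species", "ecotype", "climatic_region", "acclimation_temp_c",
        "heating_rate_c_per_h", "o2_level_pct_airsat", "ctmax_diff_c",
        "significant", "reference",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"literature table missing columns: {missing}")
    errors: list[str] = []
    entries: list[LiteratureEntry] = []
    for i, row in df.iterrows():
        sig = str(row["significant"]).strip()
        if sig not in SIGNIFICANCE_LEVELS:
            errors.append(f"row {i}: significance {sig!r} not in {SIGNIFICANCE_LEVELS}")
        o2 = row["o2_level_pct_airsat"]
        o2 = None if pd.isna(o2) else float(o2)
        if o2 is not None and o2 <= 100:
            errors.append(f"row {i}: hyperoxia O2 level must exceed 100% air sat, got {o2}")
        rate = row["heating_rate_c_per_h"]
        rate = None if pd.isna(rate) else float(rate)
        try:
            diff = float(row["ctmax_diff_c"])
        except (TypeError, ValueError):
            errors.append(f"row {i}: non-numeric ctmax_diff_c {row['ctmax_diff_c']!r}")
            continue
        entries.append(
            LiteratureEntry(
                species=str(row["species"]),
                ecotype=str(row["ecotype"]),
                climatic_region=str(row["climatic_region"]),
                acclimation_temp_c=float(row["acclimation_temp_c"]),
                heating_rate_c_per_h=rate,
                o2_level_pct_airsat=o2,
                ctmax_diff_c=diff,
                significant=sig,
                reference=str(row["reference"]),
            )
        )
    if errors:
        raise ValueError("literature table validation failed:\n" + "\n".join(errors))
    return entries


def species_aggregate(entries: list[LiteratureEntry]) -> list[SpeciesSummary]:
    """One summary per species, in first-appearance order."""
    if not entries:
        raise ValueError("no literature entries to aggregate")
    order: list[str] = []
    rows: dict[str, list[LiteratureEntry]] = {}
    for e in entries:
        if e.species not in rows:
            order.append(e.species)
            rows[e.species] = []
        rows[e.species].append(e)
    out = []
    for sp in order:
        es = rows[sp]
        max_diff = max(e.ctmax_diff_c for e in es)
        any_sig = any(e.significant == "yes" for e in es)
        untested = all(e.significant == "na" for e in es)
        out.append(
            SpeciesSummary(
                species=sp,
                n_conditions=len(es),
                max_diff=max_diff,
                any_significant=any_sig,
                increased=any_sig or (untested and max_diff > 0),
            )
        )
    return out


def prevalence_summary(summaries: list[SpeciesSummary]) -> dict:
    """Prevalence counts and the significant-difference magnitude range."""
    if not summaries:
        raise ValueError("no species summaries")
    n = len(summaries)
    sig = [s for s in summaries if s.any_significant]
    n_increased = sum(s.increased for s in summaries)
    diffs = [s.max_diff for s in sig]
    return {
        "n_species": n,
        "n_significant": len(sig),
        "n_increased": n_increased,
        "percent_increased": 100.0 * n_increased / n,
        "significant_range_c": (
            (round(min(diffs), 1), round(max(diffs), 1)) if diffs else None
        ),
        "significant_range_unrounded_c": ((min(diffs), max(diffs)) if diffs else None),
    }


def compare_ctmax(group_a, group_b) -> dict:
    """CTmax contrast between two groups (B − A): medians, means, U test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 CTmax values per group")
    u, p = mann_whitney(a, b)
    return {
        "median_diff": float(np.median(b) - np.median(a)),
        "mean_diff": float(np.mean(b) - np.mean(a)),
        "mannwhitney_u": u,
        "p": p,
        "n": (len(a), len(b)),
    }


# ---------------------------------------------------------------------------
# LT50 sigmoidal regression
# ---------------------------------------------------------------------------


def _nll_and_grad(params, temps, n, k):
    lt50, b1 = params
    eta = np.clip(b1 * (temps - lt50), -30.0, 30.0)
    p = expit(eta)
    # Binomial negative log-likelihood up to a constant.
    nll = -np.sum(k * eta - n * np.logaddexp(0.0, eta))
    resid = n * p - k
    d_lt50 = float(np.sum(resid * (-b1)))
    d_b1 = float(np.sum(resid * (temps - lt50)))
    return float(nll), np.array([d_lt50, d_b1])


def _fit_logistic(temps, n, k, scale_bounds=(0.05, 10.0)):
    temps = np.asarray(temps, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    frac = k / n
    if np.all(k == 0) or np.all(k == n):
        raise FitError("no response variation: all individuals (un)responsive")
    # Moment start: temperature where the response crosses 0.5.
    lt0 = float(np.interp(0.5, frac, temps)) if np.any(np.diff(frac) > 0) else float(
        temps[np.argmin(np.abs(frac - 0.5))]
    )
    res = minimize(
        _nll_and_grad,
        x0=np.array([lt0, 2.0]),
        args=(temps, n, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[
            (temps.min() - 20.0, temps.max() + 20.0),
            (1.0 / scale_bounds[1], 1.0 / scale_bounds[0]),
        ],
    )
    lt50, b1 = res.x
    return float(lt50), float(1.0 / b1)


def lt50_fit(
    temps,
    n_exposed,
    n_unresponsive,
    bootstrap_reps: int = 500,
    seed: int | None = None,
) -> LT50Fit:
    """LT50 by two-parameter logistic maximum likelihood.

    ``n_unresponsive[i]`` of ``n_exposed[i]`` individuals became
    unresponsive at ``temps[i]``. The 95% CI comes from a nonparametric
    bootstrap over individuals (binary outcomes resampled within each
    temperature level). Two fits whose 95% CIs do not overlap are treated as
    significantly different (see :func:`ci_separated`).
    """
    temps = np.asarray(temps, dtype=float)
    n = np.asarray(n_exposed, dtype=int)
    k = np.asarray(n_unresponsive, dtype=int)
    if len(temps) < 3:
        raise FitError("need at least 3 temperature levels")
    if np.any(k > n) or np.any(n <= 0):
        raise FitError("response counts must satisfy 0 <= k <= n, n > 0")
    lt50, scale = _fit_logistic(temps, n, k)

    rng = np.random.default_rng(seed)
    boots = []
    frac = k / n
    for _ in range(bootstrap_reps):
        kb = rng.binomial(n, frac)
        try:
            lb, _ = _fit_logistic(temps, n, kb)
        except FitError:
            continue
        boots.append(lb)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return LT50Fit(
        lt50=lt50, scale=scale, ci_low=float(lo), ci_high=float(hi),
        n_bootstrap=len(boots),
    )


def ci_separated(a: LT50Fit, b: LT50Fit) -> bool:
    """True when the two 95% confidence intervals do not overlap."""
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low
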