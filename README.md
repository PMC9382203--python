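# thermoramp

Cardiorespiratory thermal-ramping analysis for fish physiology: a tested,
reusable pipeline from raw respirometer and blood-flow traces to
whole-animal oxygen uptake, cardiac function, and acute thermal-tolerance
statistics, plus a literature synthesis of hyperoxia-induced thermal
tolerance across fishes.

## The problem

When water warms acutely, a fish's survival limit (the critical thermal
maximum, CT_max — the temperature at which it loses equilibrium) is thought
to be set by the capacity of the cardiorespiratory system to supply oxygen
to tissues. Environmental hyperoxia (O₂ supersaturation, e.g. ~200% air
saturation in densely vegetated shallow habitats) can raise that ceiling.
Quantifying the mechanism requires stitching together several measurements
made simultaneously during a stepped temperature ramp:

- **Intermittent stop-flow respirometry.** During sealed "closed" phases the
  water O₂ level declines linearly; the slope, corrected for a
  temperature-dependent background (chamber) slope and scaled by effective
  volume and body mass, gives the routine O₂ uptake
  ṀO₂ (mg O₂ kg⁻¹ h⁻¹). Routine ṀO₂ at a temperature step is the mean of
  three measurement cycles; the maximum of these step means (ṀO₂-ROU,max)
  estimates tissue O₂ supply capacity.
- **Pulsatile ventral-aortic blood flow.** Heart rate f_H comes from peak
  detection on the 10 Hz flow signal; cardiac output Q̇ is the time-mean
  flow normalised to body mass (ml min⁻¹ kg⁻¹); stroke volume
  V_S = Q̇ / f_H. Cardiac values are *tied* to the same time windows as the
  ṀO₂ cycles.
- **Fick principle.** ṀO₂ = Q̇ · (A−V O₂ content difference), rearranged to
  estimate tissue O₂ extraction: A−V O₂ = ṀO₂ / (60 · Q̇) in mg O₂ ml⁻¹.
- **Statistics.** Natural-log transforms, Welch/Student t-tests,
  Mann–Whitney U (exact enumeration for small untied samples), and a mixed
  two-way ANOVA (O₂ treatment × temperature) with the Greenhouse–Geisser
  epsilon correction for sphericity violations.
- **Tolerance synthesis.** Per-trial CT_max group comparison, a packaged
  table of published hyperoxia-vs-normoxia upper-thermal-limit comparisons
  with prevalence counting, and an LT50 logistic-regression utility with
  bootstrap confidence intervals.

Because the original animal data are not redistributable, the package ships
a first-class synthetic-trial generator (`thermoramp.synthgen`) that
emulates the full raw data stream — stepped ramps, closed/flush valve
cycles, background-contaminated O₂ declines, pulsatile flow, blood panels,
loss-of-equilibrium events — with known ground truth, so every analysis
stage is testable as a parameter-recovery problem.

## Worked example

```python
from thermoramp import CohortConfig, RunConfig, run_all

report = run_all(RunConfig(cohort=CohortConfig(seed=1), output_root="demo_run"))
g, c = report["groups"], report["contrasts"]
print(g["normoxia"]["max_mo2_mean"], g["hyperoxia"]["max_mo2_mean"])
print(c["co_pct_diff"], c["sv_pct_diff"], c["ctmax"]["mean_diff"])
```

With seed 1 this simulates 9 normoxic (~97% air saturation) and 9
hyperoxic (~209%) trout trials, analyses the raw traces end-to-end and
writes `demo_run/report.{json,md}` plus per-stage CSVs. Key numbers from
the seed-1 report:

```
normoxia  max MO2-ROU: 289.2 mg O2/kg/h at 25.1 C
hyperoxia max MO2-ROU: 452.4 mg O2/kg/h at 25.4 C
MO2 elevation: 56%   CO: +28.9%  SV: +40.9%  HR: -8.6%  A-V O2: +21.6%
CTmax: mean diff +0.84 C (median +0.91), Mann-Whitney p=4.114e-05
lactate at 26C: 4.83 vs 1.20 mM, p=1.32e-06
literature: 20 species, 9 significant, 50% increased, range 0.4-1.8 C
```

Reading this: the hyperoxic arm reaches a far higher O₂-uptake ceiling near
its thermal limit, driven mostly by a larger stroke volume (heart rate
barely differs), it accumulates much less plasma lactate approaching
CT_max, and it tolerates roughly 0.85 °C more heat. These recovered values
sit within sampling error of the generator's calibrated population values
(292.8 and 462.1 mg O₂ kg⁻¹ h⁻¹ ceilings, +33% cardiac output, +46% stroke
volume, +0.87 °C CT_max); any single cohort of 9 fish per arm scatters
around them. The literature synthesis reports that half of the 20 fish
species examined to date show increased upper thermal limits under
hyperoxia, with significant elevations spanning 0.4–1.8 °C.

The same stages are available from the shell:

```bash
thermoramp simulate --seed 1 --out cohort/      # write raw trial CSVs
thermoramp respiro  --in cohort/ --out resp/    # MO2 records + summaries
thermoramp cardio   --in cohort/ --out card/    # tied cardiac windows
thermoramp meta                                 # literature synthesis
thermoramp run --seed 1 --out demo_run          # everything + report
```

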