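"""Reading trials back from the on-disk cohort layout.

A cohort directory contains ``cohort_config.json`` plus one sub-directory
per fish with ``trace.csv`` (time_s, temp_C, o2_airsat_pct, flow_mL_min),
``events.csv`` (time_s, event), ``blood.csv`` and the ground-truth /
metadata sidecar ``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import FishTrial

__all__ = ["read_trial", "read_cohort_dir"]


def read_trial(fish_dir: str | Path) -> FishTrial:
    d = Path(fish_dir)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    return FishTrial(
        fish_id=truth["fish_id"],
        group=truth["group"],
        trace=pd.read_csv(d / "trace.csv"),
        events=pd.read_csv(d / "events.csv"),
        blood=pd.read_csv(d / "blood.csv"),
        truth=truth,
        beat_times=np.empty(0),
    )


def read_cohort_dir(root: str | Path) -> list[FishTrial]:
    root = Path(root)
    trials = [
        read_trial(p) for p in sorted(root.iterdir())
        if p.is_dir() and (p / "truth.json").exists()
    ]
    if not trials:
        raise FileNotFoundError(f"no fish directories under {root}")
    return trials
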