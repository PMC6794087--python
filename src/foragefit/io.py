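"""Reading and writing trial-by-trial cohort tables.

Cohorts are stored as a single CSV of observations (one row per patch visit
for foraging, one row per trial for ITC) plus an optional JSON sidecar with
each rat's per-condition mean state durations.  A column-mapping dict adapts
externally deposited files whose headers differ from the canonical schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .likelihood import FORAGING_COLUMNS, ITC_COLUMNS, SubjectDataset
from .task import StateDurations

__all__ = ["write_cohort", "read_cohort", "durations_path"]


def durations_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_durations.json")


def write_cohort(datasets: list[SubjectDataset], path) -> None:
    """Write a cohort to ``path`` (CSV) with a durations JSON sidecar."""
    if not datasets:
        raise ValueError("empty cohort")
    task = datasets[0].task
    frames = []
    durations = {}
    for ds in datasets:
        if ds.task != task:
            raise ValueError("mixed tasks in one cohort file")
        frames.append(ds.observations)
        durations[ds.rat_id] = {
            "experiment": ds.experiment,
            "conditions": {
                cond: {
                    "decision_s": d.decision_s,
                    "consumption_ul_per_s": d.consumption_ul_per_s,
                    "gate_s": d.gate_s,
                    "travel_s": d.travel_s,
                    "handling_s": d.handling_s,
                }
                for cond, d in ds.durations.items()
            },
        }
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    with open(durations_path(path), "w") as fh:
        json.dump({"task": task, "rats": durations}, fh, indent=1)


def _validate(df: pd.DataFrame, task: str) -> None:
    required = FORAGING_COLUMNS if task == "foraging" else ITC_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if task == "foraging":
        bad = df.index[df["harvests"] < 1]
        if len(bad):
            raise ValueError(f"harvests < 1 at row(s) {list(bad[:10])}")
    else:
        bad = df.index[~df["choice"].isin([0, 1])]
        if len(bad):
            raise ValueError(f"choice not in {{0, 1}} at row(s) {list(bad[:10])}")


def read_cohort(
    path,
    task: str | None = None,
    experiment: str | None = None,
    column_map: dict | None = None,
) -> list[SubjectDataset]:
    """Read a cohort CSV back into per-rat datasets.

    ``column_map`` maps the file's headers to the canonical schema, so
    externally deposited tables can be ingested without editing the file.
    Durations come from the JSON sidecar when present, else defaults.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    meta_path = durations_path(path)
    meta = None
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    if task is None:
        task = meta["task"] if meta else ("foraging" if "harvests" in df.columns else "itc")
    _validate(df, task)

    datasets = []
    for rat_id, grp in df.groupby("rat", sort=True):
        rat_id = str(rat_id)
        exp = experiment
        durations = {}
        if meta and rat_id in meta.get("rats", {}):
            entry = meta["rats"][rat_id]
            exp = exp or entry.get("experiment")
            for cond, dd in entry["conditions"].items():
                durations[cond] = StateDurations(
                    decision_s=dd["decision_s"],
                    consumption_ul_per_s=dd["consumption_ul_per_s"],
                    gate_s=dd.get("gate_s", 1.0),
                    travel_s=dd.get("travel_s"),
                    handling_s=dd.get("handling_s"),
                )
        if exp is None:
            exp = str(grp["experiment"].iloc[0]) if "experiment" in grp.columns else "itc"
        for cond in grp["condition"].unique():
            durations.setdefault(cond, StateDurations())
        datasets.append(
            SubjectDataset(
                task=task,
                rat_id=rat_id,
                experiment=exp,
                observations=grp.reset_index(drop=True),
                durations=durations,
            )
        )
    return datasets
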