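"""Tidy CSV / JSON interchange for cohorts, trajectories and reports."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import Event, MorphoTimeSeries, VesicleTrajectory


def write_cohort_csv(cohort: Sequence[MorphoTimeSeries], path) -> None:
    """Long-format cohort table: embryo_id, t_hpf, quantity, value, region."""
    pd.concat([m.to_tidy() for m in cohort], ignore_index=True).to_csv(
        path, index=False)


def read_cohort_csv(path) -> list[MorphoTimeSeries]:
    df = pd.read_csv(path)
    out = []
    for embryo_id, g in df.groupby("embryo_id", sort=False):
        wide = (g[g["region"].isna()]
                .pivot_table(index="t_hpf", columns="quantity", values="value"))
        h = (g[g["region"].notna()]
             .pivot_table(index="t_hpf", columns="region", values="value"))
        t = wide.index.to_numpy(float)
        P = None
        if "P" in wide:
            P = wide.reindex(columns=["P"]).to_numpy(float).ravel()
            P = np.where(np.isfinite(P), P, np.nan)
        out.append(MorphoTimeSeries(
            t=t, N=wide["N"].to_numpy(), s=wide["s"].to_numpy(),
            Vt=wide["Vt"].to_numpy(), Vl=wide["Vl"].to_numpy(),
            Vo=wide["Vo"].to_numpy(), Sl=wide["Sl"].to_numpy(),
            psi=wide["psi"].to_numpy(),
            h_medial=h["medial"].to_numpy(), h_lateral=h["lateral"].to_numpy(),
            h_poles=h["poles"].to_numpy(), P=P, embryo_id=str(embryo_id)))
    return out


def write_events_jsonl(events: Sequence[Event], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"t": e.t, "kind": e.kind,
                                 "params": e.params}) + "\n")


def read_events_jsonl(path) -> list[Event]:
    events = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            d = json.loads(line)
            events.append(Event(t=d["t"], kind=d["kind"],
                                params=d.get("params", {})))
    return events


def write_trajectory_csv(traj: VesicleTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
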