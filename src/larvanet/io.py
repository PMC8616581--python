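"""Plain-text persistence for pipeline inputs and outputs.

Formats: tracks as JSON-lines (one record per frame), stimulus and all
tabular results as CSV, connectomes as adjacency + annotation CSVs, calcium
recordings as per-trial CSVs indexed by a manifest. A YAML provenance log
records the parameters and seed of every generated dataset.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CalciumRecording, CalciumRecordingSet, HeadSweepEvent, TurnEvent

__all__ = [
    "write_provenance",
    "write_events",
    "read_events",
    "write_calcium_set",
    "read_calcium_set",
]


def write_provenance(path: str | Path, command: str, params: dict) -> None:
    """Record what generated a dataset (command, parameters, seed)."""
    from . import __version__

    doc = {"generator": f"larvanet {__version__}", "command": command, "params": params}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_events(path: str | Path, turns: list[TurnEvent]) -> None:
    """Turn + head-sweep events as a flat CSV."""
    rows = []
    for i, ev in enumerate(turns):
        rows.append(
            {
                "larva_id": ev.larva_id, "turn_index": i, "kind": "turn",
                "t_start": ev.t_start, "t_end": ev.t_end, "accepted": "", "is_first": "",
            }
        )
        for hs in ev.head_sweeps:
            rows.append(
                {
                    "larva_id": ev.larva_id, "turn_index": i, "kind": "head_sweep",
                    "t_start": hs.t_start, "t_end": hs.t_end,
                    "accepted": int(hs.accepted), "is_first": int(hs.is_first),
                }
            )
    pd.DataFrame(
        rows, columns=["larva_id", "turn_index", "kind", "t_start", "t_end", "accepted", "is_first"]
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[TurnEvent]:
    df = pd.read_csv(path)
    turns: dict[tuple, TurnEvent] = {}
    for _, row in df[df["kind"] == "turn"].iterrows():
        key = (row["larva_id"], int(row["turn_index"]))
        turns[key] = TurnEvent(
            larva_id=str(row["larva_id"]), t_start=float(row["t_start"]), t_end=float(row["t_end"])
        )
    for _, row in df[df["kind"] == "head_sweep"].iterrows():
        key = (row["larva_id"], int(row["turn_index"]))
        turns[key].head_sweeps.append(
            HeadSweepEvent(
                t_start=float(row["t_start"]),
                t_end=float(row["t_end"]),
                accepted=bool(int(row["accepted"])),
                is_first=bool(int(row["is_first"])),
                larva_id=str(row["larva_id"]),
            )
        )
    return [turns[k] for k in sorted(turns)]


def write_calcium_set(recs: CalciumRecordingSet, out_dir: str | Path) -> Path:
    """Write per-trial trace CSVs plus epochs.csv and manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    epochs_rows = []
    seen_epochs = False
    for i, rec in enumerate(recs):
        fname = f"trace_{i:03d}.csv"
        df = pd.DataFrame({"t": rec.t, "F_gcamp": rec.F_gcamp})
        if rec.F_tdtom is not None:
            df["F_tdtom"] = rec.F_tdtom
        df.to_csv(out_dir / fname, index=False)
        manifest.append(
            {"individual": rec.individual_id, "trial": rec.trial_id, "file": fname, "qc_pass": 1}
        )
        if not seen_epochs:
            epochs_rows = [{"label": l, "start": s, "end": e} for l, s, e in rec.epochs]
            seen_epochs = True
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(epochs_rows, columns=["label", "start", "end"]).to_csv(
        out_dir / "epochs.csv", index=False
    )
    return out_dir


def read_calcium_set(manifest_csv: str | Path, epochs_csv: str | Path) -> CalciumRecordingSet:
    """Load a recording set; honors QC flags and averages multi-ROI rows.

    Manifest rows with ``qc_pass`` false are dropped. Multiple rows for the
    same (individual, trial) — e.g. left/right hemisphere ROIs — have their
    fluorescence averaged before scoring. Trace rows flagged in an optional
    ``artifact`` column are discarded as motion artifacts.
    """
    manifest_csv = Path(manifest_csv)
    base = manifest_csv.parent
    manifest = pd.read_csv(manifest_csv)
    if "qc_pass" in manifest.columns:
        manifest = manifest[manifest["qc_pass"].astype(bool)]
    edf = pd.read_csv(epochs_csv)
    epochs = [(str(r["label"]), float(r["start"]), float(r["end"])) for _, r in edf.iterrows()]
    recordings = []
    for (ind, trial), group in manifest.groupby(["individual", "trial"], sort=False):
        traces = []
        for _, row in group.iterrows():
            df = pd.read_csv(base / row["file"])
            if "artifact" in df.columns:
                df = df[~df["artifact"].astype(bool)]
            traces.append(df)
        t = traces[0]["t"].to_numpy()
        F_g = np.mean([tr["F_gcamp"].to_numpy() for tr in traces], axis=0)
        F_t = (
            np.mean([tr["F_tdtom"].to_numpy() for tr in traces], axis=0)
            if all("F_tdtom" in tr.columns for tr in traces)
            else None
        )
        recordings.append(
            CalciumRecording(
                individual_id=str(ind), trial_id=str(trial), t=t,
                F_gcamp=F_g, F_tdtom=F_t, epochs=epochs,
            )
        )
    return CalciumRecordingSet(recordings)
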