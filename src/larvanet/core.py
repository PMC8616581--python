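"""Shared data containers for behavioral, connectomic, and imaging data.

The containers mirror what the upstream acquisition pipelines emit: midline
("spine") tracks from machine-vision larva tracking, light-stimulus traces,
synapse-count adjacency matrices with left/right homolog pairing, and
two-channel fluorescence recordings. They validate structural invariants on
construction and carry no analysis logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

N_SPINE_POINTS = 11

__all__ = [
    "N_SPINE_POINTS",
    "StimulusTrace",
    "Track",
    "TrackSet",
    "HeadSweepEvent",
    "TurnEvent",
    "GroundTruth",
    "PairedAdjacency",
    "CalciumRecording",
    "CalciumRecordingSet",
]


@dataclass
class StimulusTrace:
    """A light-stimulus time series: red intensity 0-255 on a uniform grid.

    The blue channel is constant in the experiments this models (it serves as
    a reference illumination) and is stored as a scalar broadcast to the grid.
    """

    t: np.ndarray
    red: np.ndarray
    blue: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.red.shape:
            raise ValueError("t and red must be 1-D arrays of equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.red < 0) or np.any(self.red > 255):
            raise ValueError("red intensities must lie in [0, 255]")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "red": self.red, "blue": np.full_like(self.t, self.blue)}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusTrace":
        df = pd.read_csv(path)
        blue = float(df["blue"].iloc[0]) if "blue" in df else 0.0
        return cls(t=df["t"].to_numpy(), red=df["red"].to_numpy(), blue=blue)


@dataclass
class Track:
    """One larva's midline trajectory at the camera frame rate.

    ``spine`` has shape (n_frames, 11, 2) with index 0 the head and index 10
    the tail; ``centroid`` is the tracked center of mass per frame.
    """

    larva_id: str
    t: np.ndarray
    spine: np.ndarray
    centroid: np.ndarray
    body_length: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.spine = np.asarray(self.spine, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        n = len(self.t)
        if self.spine.shape != (n, N_SPINE_POINTS, 2):
            raise ValueError(
                f"spine must have shape ({n}, {N_SPINE_POINTS}, 2), got {self.spine.shape}"
            )
        if self.centroid.shape != (n, 2):
            raise ValueError("centroid must have shape (n_frames, 2)")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not self.body_length > 0:
            raise ValueError("body_length must be positive")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def frame_dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def path_length(self) -> float:
        steps = np.diff(self.centroid, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    def net_displacement(self) -> float:
        d = self.centroid[-1] - self.centroid[0]
        return float(np.hypot(d[0], d[1]))


class TrackSet:
    """An ordered collection of tracks with JSON-lines persistence."""

    def __init__(self, tracks: Sequence[Track]):
        self.tracks = list(tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tr in self.tracks:
                for i in range(len(tr.t)):
                    rec = {
                        "larva_id": tr.larva_id,
                        "t": round(float(tr.t[i]), 6),
                        "spine": np.round(tr.spine[i], 4).tolist(),
                        "body_length": tr.body_length,
                    }
                    fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "TrackSet":
        frames: dict[str, list[dict]] = {}
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                frames.setdefault(rec["larva_id"], []).append(rec)
        tracks = []
        for lid, recs in frames.items():
            recs.sort(key=lambda r: r["t"])
            spine = np.array([r["spine"] for r in recs], dtype=float)
            t = np.array([r["t"] for r in recs], dtype=float)
            tracks.append(
                Track(
                    larva_id=lid,
                    t=t,
                    spine=spine,
                    centroid=spine.mean(axis=1),
                    body_length=float(recs[0]["body_length"]),
                )
            )
        return cls(tracks)


@dataclass
class HeadSweepEvent:
    """A lateral head cast within a turn; accepted if committed to."""

    t_start: float
    t_end: float
    accepted: bool
    is_first: bool
    larva_id: str = ""

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("head sweep must have t_end > t_start")


@dataclass
class TurnEvent:
    """A detected turn with its nested head sweeps."""

    larva_id: str
    t_start: float
    t_end: float
    head_sweeps: list[HeadSweepEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("turn must have t_end > t_start")
        firsts = [hs for hs in self.head_sweeps if hs.is_first]
        if self.head_sweeps and len(firsts) != 1:
            raise ValueError("exactly one head sweep per turn must be is_first")


@dataclass
class GroundTruth:
    """Simulation truth recorded alongside generated tracks.

    ``kernel_lags``/``kernel_values`` sample the true linear filter on the
    turn-triggered-average lag grid; ``rbar`` (turns/s), ``mu`` and ``sigma2``
    are the ratio-of-Gaussians nonlinearity actually used; ``turn_times`` maps
    larva id to turn-start times; ``head_sweeps`` lists simulated sweep
    outcomes; ``run_mask`` marks, per larva and frame, whether the larva was
    in a run (able to initiate a turn).
    """

    kernel_lags: np.ndarray | None = None
    kernel_values: np.ndarray | None = None
    rbar: float = 0.0
    mu: float = 0.0
    sigma2: float = 1.0
    turn_times: dict[str, np.ndarray] = field(default_factory=dict)
    head_sweeps: list[HeadSweepEvent] = field(default_factory=list)
    run_mask: np.ndarray | None = None
    frame_t: np.ndarray | None = None
    xf: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rbar < 0:
            raise ValueError("rbar must be >= 0")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")

    def all_turn_times(self) -> np.ndarray:
        if not self.turn_times:
            return np.array([])
        return np.sort(np.concatenate([np.asarray(v) for v in self.turn_times.values()]))


class PairedAdjacency:
    """A synapse-count matrix with left/right homolog pairing and annotations.

    ``counts``: square integer DataFrame, rows presynaptic, columns
    postsynaptic, indexed by neuron id. ``annotations``: one row per neuron
    with columns ``hemisphere`` (L/R), ``homolog_id`` (empty string if
    unpaired), ``class`` (MBON/LHN/KC/PN/DAN/other), ``transmitter``
    (ACh/GABA/Glu/unknown) and ``valence`` (positive/negative/none).
    """

    REQUIRED_COLUMNS = ("hemisphere", "homolog_id", "class", "transmitter", "valence")

    def __init__(self, counts: pd.DataFrame, annotations: pd.DataFrame):
        counts = counts.copy()
        annotations = annotations.copy()
        if counts.shape[0] != counts.shape[1] or not counts.index.equals(counts.columns):
            raise ValueError("counts must be square with identical row/column ids")
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate neuron ids: {dupes}")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.floor(vals)):
            raise ValueError("synapse counts must be integers")
        if np.any(vals < 0):
            bad = counts.index[(vals < 0).any(axis=1)].tolist()
            raise ValueError(f"negative synapse counts in rows: {bad}")
        for col in self.REQUIRED_COLUMNS:
            if col not in annotations.columns:
                raise ValueError(f"annotations missing column {col!r}")
        if "id" in annotations.columns:
            annotations = annotations.set_index("id")
        missing = set(counts.index) - set(annotations.index)
        if missing:
            raise ValueError(f"neurons without annotations: {sorted(missing)}")
        self._validate_pairing(annotations)
        self.counts = counts.astype(int)
        self.annotations = annotations

    @staticmethod
    def _validate_pairing(ann: pd.DataFrame) -> None:
        for nid, row in ann.iterrows():
            mate = row["homolog_id"]
            if mate in ("", None) or (isinstance(mate, float) and np.isnan(mate)):
                continue
            if mate == nid:
                raise ValueError(f"neuron {nid!r} paired with itself")
            if mate not in ann.index:
                raise ValueError(f"neuron {nid!r} paired with unknown id {mate!r}")
            if ann.loc[mate, "homolog_id"] != nid:
                raise ValueError(f"pairing not reciprocal between {nid!r} and {mate!r}")

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.counts.index)

    def is_paired(self, nid: str) -> bool:
        mate = self.annotations.loc[nid, "homolog_id"]
        return not (mate in ("", None) or (isinstance(mate, float) and np.isnan(mate)))

    def pairs(self) -> pd.DataFrame:
        """Homolog pairs as a table: pair_id, left, right, class, transmitter, valence.

        pair_id is the shared stem when ids look like "NAME L"/"NAME R",
        otherwise the lexicographically first member's id.
        """
        seen: set[str] = set()
        rows = []
        for nid in self.neuron_ids:
            if nid in seen or not self.is_paired(nid):
                continue
            mate = self.annotations.loc[nid, "homolog_id"]
            seen.update({nid, mate})
            left, right = (nid, mate) if self.annotations.loc[nid, "hemisphere"] == "L" else (mate, nid)
            stem_l, stem_r = left.rsplit(" ", 1)[0], right.rsplit(" ", 1)[0]
            pair_id = stem_l if stem_l == stem_r else min(left, right)
            ann = self.annotations.loc[left]
            rows.append(
                {
                    "pair_id": pair_id,
                    "left": left,
                    "right": right,
                    "class": ann["class"],
                    "transmitter": ann["transmitter"],
                    "valence": ann["valence"],
                }
            )
        return pd.DataFrame(rows).set_index("pair_id") if rows else pd.DataFrame(
            columns=["left", "right", "class", "transmitter", "valence"]
        )

    def unpaired_ids(self) -> list[str]:
        return [nid for nid in self.neuron_ids if not self.is_paired(nid)]

    def to_csv(self, adjacency_path: str | Path, annotations_path: str | Path) -> None:
        self.counts.to_csv(adjacency_path)
        self.annotations.rename_axis("id").to_csv(annotations_path)


@dataclass
class CalciumRecording:
    """Two-channel fluorescence for one trial of one individual.

    ``epochs`` lists stimulus windows as (label, start, end) in seconds.
    ``F_tdtom`` is optional; when present it enables ratiometric
    normalization against the structural channel.
    """

    individual_id: str
    trial_id: str
    t: np.ndarray
    F_gcamp: np.ndarray
    F_tdtom: np.ndarray | None = None
    epochs: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F_gcamp = np.asarray(self.F_gcamp, dtype=float)
        if self.F_tdtom is not None:
            self.F_tdtom = np.asarray(self.F_tdtom, dtype=float)
            if self.F_tdtom.shape != self.t.shape:
                raise ValueError("F_tdtom must match t in length")
        if self.F_gcamp.shape != self.t.shape:
            raise ValueError("F_gcamp must match t in length")
        if np.any(self.F_gcamp <= 0):
            raise ValueError("F_gcamp must be strictly positive")
        t0, t1 = self.t[0], self.t[-1]
        for label, start, end in self.epochs:
            if not (t0 <= start < end <= t1):
                raise ValueError(f"epoch {label!r} [{start}, {end}] outside trace span")


class CalciumRecordingSet:
    """Recordings across individuals/trials plus simulation truth if any."""

    def __init__(self, recordings: Sequence[CalciumRecording], truth: dict | None = None):
        self.recordings = list(recordings)
        self.truth = truth or {}

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterator[CalciumRecording]:
        return iter(self.recordings)

    def by_individual(self) -> dict[str, list[CalciumRecording]]:
        out: dict[str, list[CalciumRecording]] = {}
        for rec in self.recordings:
            out.setdefault(rec.individual_id, []).append(rec)
        return out
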