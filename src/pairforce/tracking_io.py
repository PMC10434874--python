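"""Reading, writing and validating cell tracking tables.

Canonical dialect: comma-separated with header

    frame,time_min,cell_id,parent_id,x_um,y_um,z_um[,label]

0-based integer frame indices, times in minutes, coordinates in um, empty
``parent_id`` for founder cells.  A cell id present in consecutive frames is
the same physical cell; an id appearing for the first time after frame 0
must either carry a ``parent_id`` (a birth) or is treated as a tracking gap
(excluded from the transition into which it appears, included thereafter).

The module also builds the frame-to-frame transition problems consumed by
the force inference, handling division (a mother that splits between frames
is mapped onto a *virtual cell* at the centroid of her two daughters) and
disappearance (dead or lost cells are dropped from that transition and
logged), and provides the mean-cell-diameter estimate
d = [Vol / ((4/3) pi Nc)]^(1/3) used to scale inference cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TrackingDataset",
    "TransitionProblem",
    "read_tracking",
    "write_tracking",
    "build_transitions",
    "estimate_mean_diameter",
    "trajectory_to_dataset",
    "decimate",
]

REQUIRED_COLUMNS = ["frame", "time_min", "cell_id", "parent_id",
                    "x_um", "y_um", "z_um"]
OPTIONAL_COLUMNS = ["label"]


@dataclass
class TrackingDataset:
    """Validated time-indexed table of cell positions with lineage links."""

    table: pd.DataFrame
    embryo_volume: Optional[float] = None

    def __post_init__(self):
        t = self.table.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        t["frame"] = t["frame"].astype(int)
        t["cell_id"] = t["cell_id"].astype(str)
        t["parent_id"] = t["parent_id"].fillna("").astype(str)
        for c in ("time_min", "x_um", "y_um", "z_um"):
            t[c] = t[c].astype(float)
        coords = t[["x_um", "y_um", "z_um"]].to_numpy()
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in tracking table")
        dup = t.duplicated(subset=["frame", "cell_id"])
        if dup.any():
            row = t[dup].iloc[0]
            raise ValueError(
                f"duplicate cell_id {row.cell_id!r} in frame {row.frame}")
        t = t.sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)
        frame_times = t.groupby("frame")["time_min"].agg(["min", "max"])
        if (frame_times["min"] != frame_times["max"]).any():
            raise ValueError("inconsistent time within a frame")
        times = frame_times["min"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        # lineage: a new id after the first frame must name a parent seen before,
        # or carry no parent (tracking gap; handled downstream)
        first = t.groupby("cell_id")["frame"].min()
        frames = sorted(t["frame"].unique())
        seen: set[str] = set()
        for f in frames:
            ids = set(t.loc[t["frame"] == f, "cell_id"])
            if f != frames[0]:
                for cid in ids - seen:
                    parent = t.loc[(t["frame"] == f) & (t["cell_id"] == cid),
                                   "parent_id"].iloc[0]
                    if parent and parent not in seen:
                        raise ValueError(
                            f"cell {cid!r} (first frame {f}) names unknown "
                            f"parent {parent!r}")
            seen |= ids
        self.table = t

    @property
    def frames(self) -> list[int]:
        return sorted(self.table["frame"].unique())

    @property
    def frame_interval(self) -> float:
        times = self.frame_times
        if len(times) < 2:
            raise ValueError("need at least two frames")
        return float(np.median(np.diff(times)))

    @property
    def frame_times(self) -> np.ndarray:
        return (self.table.groupby("frame")["time_min"].first()
                .sort_index().to_numpy())

    def frame_data(self, frame: int) -> tuple[list[str], np.ndarray]:
        sub = self.table[self.table["frame"] == frame]
        return (sub["cell_id"].tolist(),
                sub[["x_um", "y_um", "z_um"]].to_numpy())

    def labels(self) -> dict[str, str]:
        if "label" not in self.table.columns:
            return {}
        sub = self.table.dropna(subset=["label"])
        return dict(zip(sub["cell_id"], sub["label"].astype(str)))

    def summary(self) -> dict:
        n_frames = len(self.frames)
        counts = self.table.groupby("frame")["cell_id"].count()
        daughters = self.table.loc[self.table["parent_id"] != "", "cell_id"]
        n_div = daughters.nunique() // 2
        return {
            "n_frames": n_frames,
            "n_records": len(self.table),
            "cells_first_frame": int(counts.iloc[0]),
            "cells_last_frame": int(counts.iloc[-1]),
            "n_divisions": n_div,
        }


def read_tracking(path, embryo_volume: Optional[float] = None) -> TrackingDataset:
    """Read a canonical tracking CSV into a validated dataset."""
    table = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    return TrackingDataset(table, embryo_volume=embryo_volume)


def write_tracking(dataset: TrackingDataset, path) -> None:
    """Write a dataset back to the canonical CSV dialect."""
    dataset.table.to_csv(path, index=False)


@dataclass
class TransitionProblem:
    """One adjacent-frame inference problem.

    Entities are cells with positions at both endpoints; a dividing mother's
    target position is the centroid of her two daughters (``virtual`` flag).
    """

    t_from: float
    t_to: float
    dt: float
    ids: list[str]
    x_from: np.ndarray
    x_to: np.ndarray
    virtual: np.ndarray
    lost: list[str] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)


def build_transitions(dataset: TrackingDataset) -> list[TransitionProblem]:
    """Construct the per-adjacent-frame transition problems.

    Persisting cells map position(t-dt) -> position(t).  A mother whose two
    daughters appear at t is mapped to the daughters' centroid (virtual
    cell); a single re-identified daughter is treated as a continuation.
    Cells that disappear, and new cells without lineage, are excluded from
    that transition and logged on the problem.
    """
    frames = dataset.frames
    problems: list[TransitionProblem] = []
    for f_from, f_to in zip(frames[:-1], frames[1:]):
        ids_a, pos_a = dataset.frame_data(f_from)
        ids_b, pos_b = dataset.frame_data(f_to)
        t_a = float(dataset.table.loc[dataset.table["frame"] == f_from,
                                      "time_min"].iloc[0])
        t_b = float(dataset.table.loc[dataset.table["frame"] == f_to,
                                      "time_min"].iloc[0])
        index_a = {cid: k for k, cid in enumerate(ids_a)}
        index_b = {cid: k for k, cid in enumerate(ids_b)}
        sub_b = dataset.table[dataset.table["frame"] == f_to]
        parent_of = dict(zip(sub_b["cell_id"], sub_b["parent_id"]))

        daughters: dict[str, list[str]] = {}
        orphans: list[str] = []
        for cid in ids_b:
            if cid in index_a:
                continue
            parent = parent_of.get(cid, "")
            if parent and parent in index_a:
                daughters.setdefault(parent, []).append(cid)
            else:
                orphans.append(cid)

        ids, xf, xt, virt = [], [], [], []
        consumed: set[str] = set()
        for cid in ids_a:
            if cid in index_b:
                ids.append(cid)
                xf.append(pos_a[index_a[cid]])
                xt.append(pos_b[index_b[cid]])
                virt.append(False)
                consumed.add(cid)
        lost = []
        for mother, kids in daughters.items():
            if len(kids) > 2:
                raise ValueError(
                    f"mother {mother!r} has {len(kids)} daughters between "
                    f"frames {f_from} and {f_to}")
            if mother in consumed:
                raise ValueError(
                    f"mother {mother!r} persists into frame {f_to} alongside "
                    f"daughters {kids}")
            target = np.mean([pos_b[index_b[k]] for k in kids], axis=0)
            ids.append(mother)
            xf.append(pos_a[index_a[mother]])
            xt.append(target)
            virt.append(len(kids) == 2)
            consumed.add(mother)
        for cid in ids_a:
            if cid not in consumed:
                lost.append(cid)
        problems.append(TransitionProblem(
            t_from=t_a, t_to=t_b, dt=t_b - t_a, ids=ids,
            x_from=np.array(xf, dtype=float).reshape(-1, 3),
            x_to=np.array(xt, dtype=float).reshape(-1, 3),
            virtual=np.array(virt, dtype=bool),
            lost=lost, orphans=orphans))
    return problems


def estimate_mean_diameter(cell_count: int, volume: float) -> float:
    """Mean cell diameter from a conserved total volume.

    d = [Vol / ((4/3) pi Nc)]^(1/3): cells partition a constant embryo
    volume, so the diameter shrinks with the cube root of the cell count.
    """
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return float((volume / ((4.0 / 3.0) * np.pi * cell_count)) ** (1.0 / 3.0))


def trajectory_to_dataset(traj, label_map: Optional[dict] = None,
                          embryo_volume: Optional[float] = None) -> TrackingDataset:
    """Convert a simulated :class:`~pairforce.simulator.Trajectory` into a
    tracking dataset, so simulator output feeds inference directly."""
    rows = []
    for f, (t, pos, ids) in enumerate(zip(traj.times, traj.positions,
                                          traj.cell_ids)):
        for k, cid in enumerate(ids):
            rows.append({
                "frame": f,
                "time_min": t,
                "cell_id": cid,
                "parent_id": traj.parents.get(cid, ""),
                "x_um": pos[k, 0],
                "y_um": pos[k, 1],
                "z_um": pos[k, 2],
            })
    table = pd.DataFrame(rows)
    if label_map:
        table["label"] = table["cell_id"].map(label_map)
    return TrackingDataset(table, embryo_volume=embryo_volume)


def decimate(dataset: TrackingDataset, every: int) -> TrackingDataset:
    """Keep every ``every``-th frame (coarser sampling of the same recording),
    renumbering frames consecutively."""
    if every < 1:
        raise ValueError("every must be >= 1")
    keep = dataset.frames[::every]
    sub = dataset.table[dataset.table["frame"].isin(keep)].copy()
    renum = {f: k for k, f in enumerate(keep)}
    sub["frame"] = sub["frame"].map(renum)
    # a parent whose entire lifetime fell between kept frames is unknowable
    # at the coarser sampling; treat such births as tracking gaps
    kept_ids = set(sub["cell_id"])
    sub.loc[~sub["parent_id"].isin(kept_ids), "parent_id"] = ""
    return TrackingDataset(sub, embryo_volume=dataset.embryo_volume)
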