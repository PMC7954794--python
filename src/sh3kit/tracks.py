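"""Endocytic foci trajectory post-processing and movement metrics.

Single-particle tracking of cortical patch proteins (e.g., Sla1-GFP) yields
time-ordered (x, y) positions per focus plus the centroid of its host cell.
Internalization progress is measured as the effective distance traveled
toward the centroid; trajectory quality by a straightness index; assembly
dynamics by complete/incomplete event counts and the time by which 95% of
foci have disassembled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Track:
    """One focus trajectory within one cell."""

    track_id: str
    cell_id: str
    frames: np.ndarray  # frame numbers, strictly increasing
    xy: np.ndarray      # (n, 2) positions, px
    centroid: np.ndarray  # (2,) host-cell centroid, px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if len(self.frames) == 0:
            raise ValueError(f"track {self.track_id}: empty")
        if (np.diff(self.frames) <= 0).any():
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if self.xy.shape != (len(self.frames), 2):
            raise ValueError(f"track {self.track_id}: xy shape mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    def distances_to_centroid(self) -> np.ndarray:
        return np.linalg.norm(self.xy - self.centroid, axis=1)


def filter_tracks(tracks: Sequence[Track], min_frames: int = 10) -> list[Track]:
    """Drop trajectories detected in fewer than `min_frames` frames
    (spurious short detections)."""
    return [t for t in tracks if t.n_frames >= min_frames]


def trim_track(track: Track, tolerance_px: float = 2.0) -> Track:
    """Trim spurious outward segments after the point of closest approach.

    Finds the frame of minimum distance to the centroid; after it, frames
    are removed from the first frame whose distance exceeds the minimum plus
    `tolerance_px` onward. Frames before the minimum are always retained.
    """
    d = track.distances_to_centroid()
    i_min = int(np.argmin(d))
    cut = len(d)
    for j in range(i_min + 1, len(d)):
        if d[j] > d[i_min] + tolerance_px:
            cut = j
            break
    if cut == len(d):
        return track
    return replace(track, frames=track.frames[:cut], xy=track.xy[:cut])


def effective_distance(track: Track) -> np.ndarray:
    """Per-frame effective distance traveled toward the centroid:
    e(t) = d(start, centroid) - d(position(t), centroid)."""
    d = track.distances_to_centroid()
    return d[0] - d


def effective_distance_series(tracks: Sequence[Track]) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort effective-distance dynamics.

    Returns a per-frame table (frame, mean effective distance, number of
    tracks still present) and a per-track Series of final effective
    distances.
    """
    rows = []
    finals = {}
    for t in tracks:
        e = effective_distance(t)
        # time axis relative to each track's first frame
        for k, val in enumerate(e):
            rows.append({"frame": k, "effective_distance": val})
        finals[t.track_id] = float(e[-1])
    df = pd.DataFrame(rows)
    series = (
        df.groupby("frame")["effective_distance"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_effective_distance", "count": "n_tracks"})
        .reset_index()
    )
    return series, pd.Series(finals, name="final_effective_distance")


def completion_stats(
    tracks: Sequence[Track], acquisition_end: int, quantile: float = 0.95
) -> dict:
    """Complete/incomplete event counts and the disassembly quantile time.

    A track is complete when it ends strictly before the final acquisition
    frame. t95 is the earliest frame by which at least `quantile` of all
    tracks have ended (NaN when never reached, e.g., no disassembly).
    """
    ends = np.array([t.end_frame for t in tracks])
    complete = ends < acquisition_end
    n = len(ends)
    t_q = float("nan")
    if n and complete.sum() / n >= quantile:
        # earliest frame by which >= quantile of ALL tracks have ended:
        # the k-th smallest completed end frame with k = ceil(quantile * n)
        k = int(np.ceil(quantile * n))
        t_q = float(np.sort(ends[complete])[k - 1])
    return {
        "n_tracks": n,
        "n_complete": int(complete.sum()),
        "n_incomplete": int(n - complete.sum()),
        "t_disassembly_quantile": t_q,
    }


def straightness(track: Track) -> float:
    """Net displacement over path length, in [0, 1]; NaN for zero path."""
    if track.n_frames < 2:
        raise ValueError("straightness needs at least two frames")
    steps = np.diff(track.xy, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    if path == 0:
        return float("nan")
    net = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    return net / path


def track_metrics(
    tracks: Sequence[Track],
    acquisition_end: int,
    min_frames: int = 10,
    tolerance_px: float = 2.0,
) -> pd.DataFrame:
    """Filter, trim and summarize a track cohort into a per-track table."""
    kept = [trim_track(t, tolerance_px) for t in filter_tracks(tracks, min_frames)]
    rows = []
    for t in kept:
        e = effective_distance(t)
        rows.append({
            "track_id": t.track_id,
            "cell_id": t.cell_id,
            "n_frames": t.n_frames,
            "end_frame": t.end_frame,
            "complete": t.end_frame < acquisition_end,
            "effective_distance": float(e[-1]),
            "straightness": straightness(t) if t.n_frames >= 2 else float("nan"),
        })
    return pd.DataFrame(rows)


def read_tracks(track_path: str, cell_path: str) -> list[Track]:
    """Read tracks from TSVs: (track_id, cell_id, frame, x, y) and
    (cell_id, centroid_x, centroid_y)."""
    pts = pd.read_csv(track_path, sep="\t")
    cells = pd.read_csv(cell_path, sep="\t").set_index("cell_id")
    out = []
    for tid, sub in pts.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        cid = sub["cell_id"].iloc[0]
        out.append(Track(
            track_id=str(tid), cell_id=str(cid),
            frames=sub["frame"].to_numpy(),
            xy=sub[["x", "y"]].to_numpy(),
            centroid=cells.loc[cid, ["centroid_x", "centroid_y"]].to_numpy(dtype=float),
        ))
    return out


def write_tracks(tracks: Sequence[Track], track_path: str, cell_path: str) -> None:
    rows = []
    cells = {}
    for t in tracks:
        cells[t.cell_id] = t.centroid
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append({"track_id": t.track_id, "cell_id": t.cell_id,
                         "frame": int(f), "x": x, "y": y})
    pd.DataFrame(rows).to_csv(track_path, sep="\t", index=False)
    pd.DataFrame(
        [{"cell_id": cid, "centroid_x": c[0], "centroid_y": c[1]}
         for cid, c in sorted(cells.items())]
    ).to_csv(cell_path, sep="\t", index=False)
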