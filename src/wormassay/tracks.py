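"""Chemotaxis track tables and the per-worm outcome statistic.

The assay outcome is, for each worm, the mean Euclidean distance from the
salt-gradient peak averaged over every frame in the final minute of the
recording.  Tracker dropouts (a worm leaving the camera field, two worms
intersecting) are handled by carry-forward imputation: the last available
position is repeated until the worm is re-detected, and frames before a
worm's first detection are excluded rather than back-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssayGeometry",
    "OutcomeRecord",
    "parse_tracks",
    "write_tracks",
    "impute_carry_forward",
    "worm_outcome",
    "plate_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "track_id": "track_id",
    "frame": "frame",
    "x": "x_mm",
    "y": "y_mm",
    "time": "time_s",
}


@dataclass(frozen=True)
class AssayGeometry:
    """Plate geometry and scoring window of one chemotaxis assay.

    The outcome window is the closed final ``window_length_s`` of the
    recording; with the standard 7 min at 3.75 fps and a 60 s window this
    maps to the last 225 frames.
    """

    peak_xy_mm: tuple[float, float]
    start_xy_mm: tuple[float, float] = (0.0, 0.0)
    assay_duration_s: float = 420.0
    frame_rate_fps: float = 3.75
    window_length_s: float = 60.0

    def __post_init__(self) -> None:
        if self.window_length_s > self.assay_duration_s:
            raise ValueError("window_length_s cannot exceed assay_duration_s")

    @property
    def n_frames(self) -> int:
        return int(round(self.assay_duration_s * self.frame_rate_fps))

    @property
    def window_frames(self) -> tuple[int, int]:
        """Inclusive (first, last) frame index of the scoring window."""
        first = int(round((self.assay_duration_s - self.window_length_s) * self.frame_rate_fps))
        return first, self.n_frames - 1


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-worm chemotaxis outcome: mean distance (mm) from the salt peak
    over the scoring window, with frame bookkeeping."""

    track_id: object
    mean_distance_mm: float
    n_frames_in_window: int
    n_imputed_frames: int


def parse_tracks(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a tracker-export CSV into a normalized track table.

    The default dialect has columns ``track_id, frame, time_s, x_mm, y_mm``;
    ``column_map`` remaps {"track_id", "frame", "x", "y", "time"} to other
    header names.  Rows with unparseable or blank coordinates are kept but
    marked undetected.  Duplicate (track_id, frame) pairs are a validation
    error.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    missing = [cmap[k] for k in ("track_id", "frame", "x", "y") if cmap[k] not in df.columns]
    if missing:
        raise ValueError(f"track file is missing mandatory columns: {missing}")
    out = pd.DataFrame(
        {
            "track_id": df[cmap["track_id"]],
            "frame": pd.to_numeric(df[cmap["frame"]], errors="raise").astype(int),
            "x_mm": pd.to_numeric(df[cmap["x"]], errors="coerce"),
            "y_mm": pd.to_numeric(df[cmap["y"]], errors="coerce"),
        }
    )
    if cmap["time"] in df.columns:
        out["time_s"] = pd.to_numeric(df[cmap["time"]], errors="coerce")
    else:
        out["time_s"] = np.nan
    dup = out.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        offenders = out.loc[dup, ["track_id", "frame"]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate (track_id, frame) rows: {offenders[:10]}")
    out["detected"] = out["x_mm"].notna() & out["y_mm"].notna()
    out = out.sort_values(["track_id", "frame"], ignore_index=True)
    return out[["track_id", "frame", "time_s", "x_mm", "y_mm", "detected"]]


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    """Write a track table in the default CSV dialect (undetected frames get
    blank coordinates)."""
    out = table[["track_id", "frame", "time_s", "x_mm", "y_mm"]].copy()
    und = ~table["detected"].to_numpy(bool)
    out.loc[und, ["x_mm", "y_mm"]] = np.nan
    out.to_csv(path, index=False)


def impute_carry_forward(
    track: pd.DataFrame, frame_range: tuple[int, int]
) -> pd.DataFrame | None:
    """Gap-free position series for one track over an inclusive frame range.

    Every frame from the worm's first detection (or the range start, if
    later) to the range end gets a position; undetected frames repeat the
    most recent detected position.  Frames before first detection are
    excluded, never back-filled.  Returns None (with a warning) if the track
    has no detection at or before the range end.
    """
    first_f, last_f = frame_range
    det = track.loc[track["detected"] & (track["frame"] <= last_f)]
    if det.empty:
        logger.warning(
            "track %s has no detected frame at or before frame %d; excluded",
            track["track_id"].iloc[0] if len(track) else "?",
            last_f,
        )
        return None
    start = max(first_f, int(det["frame"].min()))
    frames = np.arange(start, last_f + 1)
    series = (
        det.set_index("frame")[["x_mm", "y_mm"]]
        .reindex(np.arange(int(det["frame"].min()), last_f + 1))
        .ffill()
        .loc[frames]
    )
    imputed = ~np.isin(frames, det["frame"].to_numpy())
    return pd.DataFrame(
        {
            "frame": frames,
            "x_mm": series["x_mm"].to_numpy(),
            "y_mm": series["y_mm"].to_numpy(),
            "imputed": imputed,
        }
    )


def worm_outcome(track: pd.DataFrame, geometry: AssayGeometry) -> OutcomeRecord | None:
    """Mean distance from the peak over the final-minute window for one worm.

    A worm last seen before the window still contributes through terminal
    carry-forward of its last position; a worm never detected before the
    window's end is excluded (None).
    """
    w_first, w_last = geometry.window_frames
    series = impute_carry_forward(track, (w_first, w_last))
    if series is None or series.empty:
        return None
    px, py = geometry.peak_xy_mm
    dist = np.hypot(series["x_mm"].to_numpy() - px, series["y_mm"].to_numpy() - py)
    return OutcomeRecord(
        track_id=track["track_id"].iloc[0],
        mean_distance_mm=float(dist.mean()),
        n_frames_in_window=int(len(series)),
        n_imputed_frames=int(series["imputed"].sum()),
    )


def plate_summary(
    tracks: pd.DataFrame, geometry: AssayGeometry
) -> tuple[pd.DataFrame, dict]:
    """Per-worm outcomes and the plate aggregate (worms weighted equally).

    Returns (records, aggregate) where records has one row per retained
    track and aggregate holds the plate mean/SD, worm count, and the number
    of tracks excluded for having no usable frames.
    """
    records = []
    n_excluded = 0
    if tracks.empty:
        logger.warning("empty track table: nothing to summarize")
    for _, track in tracks.groupby("track_id", sort=True):
        rec = worm_outcome(track, geometry)
        if rec is None:
            n_excluded += 1
        else:
            records.append(rec)
    rec_df = pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "mean_distance_mm": r.mean_distance_mm,
                "n_frames_in_window": r.n_frames_in_window,
                "n_imputed_frames": r.n_imputed_frames,
            }
            for r in records
        ],
        columns=["track_id", "mean_distance_mm", "n_frames_in_window", "n_imputed_frames"],
    )
    values = rec_df["mean_distance_mm"].to_numpy(float)
    aggregate = {
        "n_worms": int(len(values)),
        "n_excluded": n_excluded,
        "mean_distance_mm": float(values.mean()) if len(values) else float("nan"),
        "sd_distance_mm": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
    }
    return rec_df, aggregate
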