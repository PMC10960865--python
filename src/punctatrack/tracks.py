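"""Migration statistics from cell-track tables.

Operates on TrackMate-style CSV exports (columns ``TRACK_ID``, ``FRAME``,
``POSITION_X``, ``POSITION_Y``, optionally ``POSITION_T``; positions in µm,
time in min) and computes the standard 2-D migration metrics:

- mean speed: total path length D divided by elapsed time (µm/min)
- MSD(lag): mean square displacement, time-averaged over all start points
  within a track and then ensemble-averaged over tracks
- persistence ratio d/D: net displacement over cumulative path length, a
  curve over elapsed time in [0, 1] (1 = perfectly straight)
- forward migration index y/D: net displacement projected on the
  chemoattractant axis over path length, in [-1, 1]

plus the exponential-growth doubling time used for proliferation assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, InvalidParamsError

REQUIRED_COLUMNS = ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")


@dataclass
class Track:
    """One cell's time-ordered positions in physical units."""

    track_id: str
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_min) == len(self.x_um) == len(self.y_um)):
            raise InvalidParamsError("t, x, y must have equal length")
        if len(self.t_min) < 2:
            raise InvalidParamsError("a track needs at least 2 points")
        if np.any(np.diff(self.t_min) <= 0):
            raise InvalidParamsError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_min)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x_um), np.diff(self.y_um))

    def path_length(self) -> float:
        """Total path length D (µm)."""
        return float(self.step_lengths().sum())

    def net_displacement(self) -> float:
        """Net displacement d from first to last point (µm)."""
        return float(math.hypot(self.x_um[-1] - self.x_um[0], self.y_um[-1] - self.y_um[0]))


def _bridge(frames: np.ndarray, xs: np.ndarray, ys: np.ndarray):
    """Linearly interpolate positions at missing integer frames."""
    full = np.arange(frames[0], frames[-1] + 1)
    return full, np.interp(full, frames, xs), np.interp(full, frames, ys)


def read_tracks(
    table,
    interval_min: float | None = None,
    gap_policy: str = "bridge",
) -> list[Track]:
    """Parse a TrackMate-style table into Track objects.

    ``table`` is a CSV path or a DataFrame. Rows are grouped by TRACK_ID and
    sorted by FRAME; extra columns are ignored. Time stamps come from
    ``FRAME * interval_min``, or from a POSITION_T column (minutes) when no
    interval is given. Gaps (missing frames) are linearly interpolated under
    the default ``"bridge"`` policy, or the track is split into gap-free
    sub-tracks under ``"split"``. Tracks with fewer than 2 points are
    dropped with a warning; duplicate (track, frame) rows are an error.
    """
    if gap_policy not in ("bridge", "split"):
        raise InvalidParamsError(f"gap_policy must be 'bridge' or 'split', got {gap_policy!r}")
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if interval_min is None and "POSITION_T" not in df.columns:
        raise FormatError("supply interval_min or include a POSITION_T column")
    for col in ("FRAME", "POSITION_X", "POSITION_Y"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df.duplicated(subset=["TRACK_ID", "FRAME"]).any():
        raise FormatError("duplicate (TRACK_ID, FRAME) rows")

    tracks: list[Track] = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        grp = grp.sort_values("FRAME")
        frames = grp["FRAME"].to_numpy()
        xs = grp["POSITION_X"].to_numpy(dtype=float)
        ys = grp["POSITION_Y"].to_numpy(dtype=float)
        if len(frames) < 2:
            warnings.warn(f"track {tid!r} has <2 points and was dropped", stacklevel=2)
            continue
        has_gap = np.any(np.diff(frames) != 1)
        pieces = []
        if has_gap and gap_policy == "bridge":
            warnings.warn(f"track {tid!r}: gap(s) bridged by linear interpolation", stacklevel=2)
            frames, xs, ys = _bridge(frames, xs, ys)
            pieces.append((str(tid), frames, xs, ys))
        elif has_gap:  # split
            cuts = np.flatnonzero(np.diff(frames) != 1) + 1
            for j, (f, x, y) in enumerate(
                zip(np.split(frames, cuts), np.split(xs, cuts), np.split(ys, cuts))
            ):
                if len(f) < 2:
                    warnings.warn(
                        f"track {tid!r} fragment {j} has <2 points and was dropped",
                        stacklevel=2,
                    )
                    continue
                pieces.append((f"{tid}.{j}", f, x, y))
        else:
            pieces.append((str(tid), frames, xs, ys))
        for name, f, x, y in pieces:
            if interval_min is not None:
                t = f * float(interval_min)
            else:
                t = np.interp(f, grp["FRAME"], grp["POSITION_T"])
            tracks.append(Track(name, t, x, y))
    return tracks


def mean_speed(track: Track) -> float:
    """Total path length divided by elapsed time (µm/min)."""
    elapsed = track.t_min[-1] - track.t_min[0]
    if elapsed <= 0:
        raise DegenerateInputError("zero elapsed time")
    return track.path_length() / elapsed


def msd_curve(tracks: list[Track], max_lag: int) -> pd.DataFrame:
    """Ensemble mean square displacement by lag.

    Within each track the squared displacement at lag k frames is averaged
    over all (overlapping) start points; the per-track values are then
    averaged over tracks with equal weight. Requires regular sampling (as
    produced by read_tracks with the bridge policy). Returns a DataFrame
    with columns ``lag_frames``, ``lag_min``, ``msd_um2``; MSD(0) = 0.
    """
    if not tracks:
        raise InvalidParamsError("no tracks")
    shortest = min(len(t) for t in tracks)
    if not (1 <= max_lag < shortest):
        raise InvalidParamsError(
            f"max_lag must be in [1, {shortest - 1}] (shortest track has {shortest} points)"
        )
    dt = float(np.median(np.diff(tracks[0].t_min)))
    per_lag = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        vals = []
        for tr in tracks:
            p = tr.positions
            d = p[k:] - p[:-k]
            vals.append(np.mean(np.sum(d * d, axis=1)))
        per_lag[k] = np.mean(vals)
    return pd.DataFrame(
        {
            "lag_frames": np.arange(max_lag + 1),
            "lag_min": np.arange(max_lag + 1) * dt,
            "msd_um2": per_lag,
        }
    )


def persistence_ratio_curve(track: Track) -> pd.DataFrame:
    """d/D versus elapsed time for one track.

    At each time point t > 0, the net displacement from the start divided by
    the cumulative path length up to t. Points where the cell has not moved
    (D = 0) are excluded (NaN). Values lie in [0, 1].
    """
    p = track.positions
    d = np.hypot(p[1:, 0] - p[0, 0], p[1:, 1] - p[0, 1])
    cum = np.cumsum(track.step_lengths())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(cum > 0, d / np.where(cum > 0, cum, 1.0), np.nan)
    return pd.DataFrame(
        {"t_min": track.t_min[1:] - track.t_min[0], "d_over_D": np.clip(ratio, 0.0, 1.0)}
    )


def persistence_ratio(track: Track) -> float:
    """Final-time d/D of one track (NaN if the cell never moved)."""
    return float(persistence_ratio_curve(track)["d_over_D"].iloc[-1])


def forward_migration_index(track: Track, axis=(0.0, 1.0)) -> float:
    """Forward migration index y/D along a gradient axis.

    Net displacement projected on the (normalized) axis, divided by total
    path length. Returns NaN with a warning for a track that never moved.
    """
    ax = np.asarray(axis, dtype=float)
    norm = float(np.hypot(*ax))
    if norm == 0:
        raise InvalidParamsError("axis must be non-zero")
    ax = ax / norm
    D = track.path_length()
    if D == 0:
        warnings.warn(f"track {track.track_id!r} has zero path length; FMI undefined", stacklevel=2)
        return float("nan")
    net = track.positions[-1] - track.positions[0]
    return float(np.dot(net, ax) / D)


def summarize_tracks(tracks: list[Track], axis=(0.0, 1.0)) -> pd.DataFrame:
    """Per-track speed, final d/D, and FMI as one tidy table."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr in tracks:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "n_points": len(tr),
                    "speed_um_min": mean_speed(tr),
                    "persistence_ratio": persistence_ratio(tr),
                    "fmi": forward_migration_index(tr, axis),
                }
            )
    return pd.DataFrame(rows)


def doubling_time(n0: float, nf: float, elapsed_h: float) -> float:
    """Exponential-growth doubling time: elapsed * ln 2 / ln(nf / n0) (hours)."""
    if n0 <= 0 or elapsed_h <= 0:
        raise InvalidParamsError("n0 and elapsed time must be positive")
    if nf <= n0:
        raise DegenerateInputError("no growth: final count must exceed initial count")
    return elapsed_h * math.log(2.0) / math.log(nf / n0)
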