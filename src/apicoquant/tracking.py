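"""Endosome tracking and apical/basal classification.

Per-frame detections (in μm, y increasing basally) are linked frame-to-
frame by a globally optimal one-to-one assignment minimizing total
Euclidean displacement, with a hard distance gate and no gap closing.
Tracks are then filtered — duration of six frames or more, origin within
5 μm of the apical membrane — and classified: tracks whose maximal depth
below the apical reference exceeds 5 μm descend basally; the rest persist
apically.  Maximal depth per track is profiled by cellularization stage
against the advancing furrow front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger("apicoquant")

LABEL_PERSISTENT = "persistent"
LABEL_DESCENDING = "descending"


@dataclass(frozen=True)
class TrackingParams:
    """Linking gate and the duration/origin/descent criteria.

    ``max_link_dist_um`` is the hard per-frame-pair gate; a candidate
    link longer than the gate is refused.  ``min_duration_frames`` and
    ``apical_band_um`` implement the track filters (duration ≥ 6 frames,
    origin within 5 μm of the apical membrane, inclusive) and the
    persistent/descending split (descending = max depth past the band).
    """

    max_link_dist_um: float = 2.0
    min_duration_frames: int = 6
    apical_band_um: float = 5.0
    apical_reference_um: float | str = "auto"

    def __post_init__(self) -> None:
        if not (self.max_link_dist_um > 0):
            raise ValueError("max_link_dist_um must be > 0")
        if self.min_duration_frames < 1:
            raise ValueError("min_duration_frames must be ≥ 1")
        if not (self.apical_band_um > 0):
            raise ValueError("apical_band_um must be > 0")


@dataclass(frozen=True)
class Detection:
    """A single particle detection in a sagittal frame (μm coordinates)."""

    t: int
    y_um: float
    x_um: float
    intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("frame index must be ≥ 0")


def detections_table(detections: "list[Detection]") -> pd.DataFrame:
    """Stack :class:`Detection` records into the tabular linker input."""
    return pd.DataFrame(
        [(d.t, d.y_um, d.x_um, d.intensity) for d in detections],
        columns=["t", "y_um", "x_um", "intensity"],
    )


@dataclass(frozen=True)
class Track:
    """One linked trajectory; detections at strictly consecutive frames."""

    track_id: int
    t: np.ndarray
    y_um: np.ndarray
    x_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=int)
        if t.size < 1:
            raise ValueError("track must contain at least one detection")
        if t.size > 1 and not np.all(np.diff(t) == 1):
            raise ValueError("track frames must be strictly consecutive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y_um", np.asarray(self.y_um, dtype=float))
        object.__setattr__(self, "x_um", np.asarray(self.x_um, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))

    @property
    def duration_frames(self) -> int:
        return int(self.t.size)

    def origin_depth_um(self, apical_reference_um: float) -> float:
        return float(self.y_um[0] - apical_reference_um)

    def max_depth_um(self, apical_reference_um: float) -> float:
        return float(np.max(self.y_um - apical_reference_um))

    def net_displacement_um(self) -> float:
        """Start-to-end Euclidean displacement (secondary readout)."""
        return float(
            np.hypot(self.y_um[-1] - self.y_um[0], self.x_um[-1] - self.x_um[0])
        )


@dataclass(frozen=True)
class TrackSet:
    tracks: tuple[Track, ...]
    apical_reference_um: float

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def summary(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "t_start": int(tr.t[0]),
                    "duration_frames": tr.duration_frames,
                    "origin_depth_um": tr.origin_depth_um(self.apical_reference_um),
                    "max_depth_um": tr.max_depth_um(self.apical_reference_um),
                    "net_displacement_um": tr.net_displacement_um(),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "track_id",
                "t_start",
                "duration_frames",
                "origin_depth_um",
                "max_depth_um",
                "net_displacement_um",
            ],
        )


@dataclass(frozen=True)
class FurrowSeries:
    """Furrow-front depth below the apical reference, per frame (μm)."""

    depth_um: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_um, dtype=float)
        if d.size and d.min() < 0:
            raise ValueError("furrow depth must be non-negative")
        if d.size > 1 and np.any(np.diff(d) < 0):
            raise ValueError("furrow depth must be non-decreasing in time")
        object.__setattr__(self, "depth_um", d)


# --------------------------------------------------------------------------
# apical reference
# --------------------------------------------------------------------------

def estimate_apical_reference(frame: np.ndarray, pixel_size_um: float) -> float:
    """Apical membrane position (μm) from a sagittal frame.

    The membrane is the dominant bright structure, so the reference is
    the intensity-weighted mean row of the brightest 1% of pixels.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D sagittal frame")
    cutoff = np.quantile(frame, 0.99)
    bright = frame >= cutoff
    weights = frame[bright]
    rows = np.nonzero(bright)[0]
    return float(np.average(rows, weights=weights) * pixel_size_um)


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def _pair_assignment(
    prev_xy: np.ndarray, next_xy: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Min-total-displacement one-to-one matching within the gate.

    Augmented square assignment: each detection can instead link to a
    birth/death dummy at cost = gate, so every gated link that can be
    made is made (a link costs ≤ gate < 2·gate, the price of leaving both
    endpoints unmatched) and ties in cardinality resolve to the smallest
    total displacement.
    """
    n, m = len(prev_xy), len(next_xy)
    if n == 0 or m == 0:
        return []
    dist = cdist(prev_xy, next_xy)
    feasible = dist <= gate
    if not feasible.any():
        return []
    BIG = np.inf
    size = n + m
    cost = np.full((size, size), BIG)
    cost[:n, :m] = np.where(feasible, dist, BIG)
    cost[np.arange(n), m + np.arange(n)] = gate  # death of a previous track
    cost[n + np.arange(m), np.arange(m)] = gate  # birth of a new track
    # lower-right dummy-dummy block at zero cost keeps the augmented
    # problem always solvable
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    links = []
    for r, c in zip(rows, cols):
        if r < n and c < m and feasible[r, c]:
            links.append((int(r), int(c)))
    return links


def link_detections(
    detections: pd.DataFrame, params: TrackingParams | None = None
) -> TrackSet:
    """Link per-frame detections into gap-free trajectories.

    ``detections`` needs columns ``t, y_um, x_um`` (``intensity``
    optional).  For each consecutive frame pair the globally optimal
    one-to-one assignment minimizing total Euclidean displacement among
    within-gate pairs is used; unmatched detections start new tracks and
    tracks end as soon as they go unmatched (no gap closing).  The
    apical reference must be numeric in ``params`` or supplied later via
    :func:`with_reference`.
    """
    if params is None:
        params = TrackingParams()
    df = detections.copy()
    required = {"t", "y_um", "x_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"detections need columns {sorted(required)}")
    if "intensity" not in df.columns:
        df["intensity"] = np.nan
    if len(df) == 0:
        ref = params.apical_reference_um
        return TrackSet(tracks=(), apical_reference_um=float(ref) if ref != "auto" else np.nan)
    # canonical within-frame order makes the result independent of input
    # row order
    df = df.sort_values(["t", "y_um", "x_um"], kind="mergesort").reset_index(drop=True)
    t_min, t_max = int(df["t"].min()), int(df["t"].max())
    by_frame = {int(t): g for t, g in df.groupby("t")}

    track_rows: list[list[tuple[int, float, float, float]]] = []
    active: dict[int, int] = {}  # detection row index within frame -> track index
    prev_frame: pd.DataFrame | None = None
    for t in range(t_min, t_max + 1):
        cur = by_frame.get(t)
        if cur is None:
            active = {}
            prev_frame = None
            continue
        cur_xy = cur[["y_um", "x_um"]].to_numpy()
        new_active: dict[int, int] = {}
        if prev_frame is not None and active:
            prev_xy = prev_frame[["y_um", "x_um"]].to_numpy()
            links = _pair_assignment(prev_xy, cur_xy, params.max_link_dist_um)
            for r, c in links:
                if r in active:
                    idx = active[r]
                    row = cur.iloc[c]
                    track_rows[idx].append(
                        (t, row["y_um"], row["x_um"], row["intensity"])
                    )
                    new_active[c] = idx
        for c in range(len(cur)):
            if c not in new_active:
                row = cur.iloc[c]
                track_rows.append([(t, row["y_um"], row["x_um"], row["intensity"])])
                new_active[c] = len(track_rows) - 1
        active = new_active
        prev_frame = cur

    ref = params.apical_reference_um
    ref_value = float(ref) if ref != "auto" else np.nan
    tracks = []
    for i, rows in enumerate(track_rows):
        arr = np.asarray(rows, dtype=float)
        tracks.append(
            Track(
                track_id=i,
                t=arr[:, 0].astype(int),
                y_um=arr[:, 1],
                x_um=arr[:, 2],
                intensity=arr[:, 3],
            )
        )
    tracks.sort(key=lambda tr: (int(tr.t[0]), float(tr.y_um[0]), float(tr.x_um[0])))
    tracks = [
        Track(track_id=i, t=tr.t, y_um=tr.y_um, x_um=tr.x_um, intensity=tr.intensity)
        for i, tr in enumerate(tracks)
    ]
    logger.info(
        "link_detections: %d detections -> %d tracks (gate %.2f um)",
        len(df), len(tracks), params.max_link_dist_um,
    )
    return TrackSet(tracks=tuple(tracks), apical_reference_um=ref_value)


def with_reference(trackset: TrackSet, apical_reference_um: float) -> TrackSet:
    return TrackSet(tracks=trackset.tracks, apical_reference_um=float(apical_reference_um))


# --------------------------------------------------------------------------
# filtering, classification, profiling
# --------------------------------------------------------------------------

def filter_tracks(
    trackset: TrackSet, params: TrackingParams | None = None
) -> TrackSet:
    """Keep tracks lasting ≥ 6 frames with an origin within 5 μm of the
    apical membrane (both bounds inclusive, both configurable)."""
    if params is None:
        params = TrackingParams()
    ref = trackset.apical_reference_um
    if not np.isfinite(ref):
        raise ValueError("apical reference must be resolved before filtering")
    kept = tuple(
        tr
        for tr in trackset.tracks
        if tr.duration_frames >= params.min_duration_frames
        and tr.origin_depth_um(ref) <= params.apical_band_um
    )
    logger.info(
        "filter_tracks: kept %d / %d (duration >= %d, origin <= %.1f um)",
        len(kept), len(trackset.tracks), params.min_duration_frames,
        params.apical_band_um,
    )
    return TrackSet(tracks=kept, apical_reference_um=ref)


def classify_tracks(
    trackset: TrackSet, params: TrackingParams | None = None
) -> pd.DataFrame:
    """Label each track descending (max depth past the apical band) or
    persistent (stays within it).  Returns the track summary with a
    ``label`` column."""
    if params is None:
        params = TrackingParams()
    ref = trackset.apical_reference_um
    if len(trackset) and not np.isfinite(ref):
        raise ValueError("apical reference must be resolved before classification")
    summary = trackset.summary()
    if summary.empty:
        summary["label"] = pd.Series(dtype=object)
        return summary
    summary["label"] = np.where(
        summary["max_depth_um"] > params.apical_band_um,
        LABEL_DESCENDING,
        LABEL_PERSISTENT,
    )
    return summary


def displacement_profile(
    labelled: pd.DataFrame,
    windows: list[tuple[str, float, float]],
    furrow: FurrowSeries,
    frame_interval_s: float,
) -> pd.DataFrame:
    """Stage profile of maximal track depth against furrow position.

    Each track is assigned to the stage window containing its first
    frame's time; windows are ``(label, start_s, end_s)`` with end
    exclusive (the final window's end inclusive) and must jointly cover
    the movie.  Per window and class the table reports n, mean and
    population SD of ``max_depth_um`` plus the window-mean furrow depth;
    windows with no tracks of a class report n=0 and missing means.
    """
    if not windows:
        raise ValueError("at least one stage window required")
    windows = sorted(windows, key=lambda w: w[1])
    T = furrow.depth_um.size
    times = np.arange(T) * frame_interval_s
    covered = np.zeros(T, dtype=bool)
    for _, start, end in windows:
        covered |= (times >= start) & (times < end)
    covered |= times == windows[-1][2]
    if not covered.all():
        raise ValueError("stage windows do not cover every movie frame")

    def window_of(time_s: float) -> str:
        for label, start, end in windows:
            if start <= time_s < end:
                return label
        if time_s == windows[-1][2]:
            return windows[-1][0]
        raise ValueError(f"track start {time_s} s outside all stage windows")

    rows = []
    for label, start, end in windows:
        in_win = (times >= start) & (times < end)
        if (label, start, end) == windows[-1]:
            in_win |= times == end
        furrow_mean = float(furrow.depth_um[in_win].mean()) if in_win.any() else np.nan
        for cls in (LABEL_PERSISTENT, LABEL_DESCENDING):
            if labelled.empty:
                depths = np.array([])
            else:
                starts = labelled["t_start"].to_numpy() * frame_interval_s
                sel = (labelled["label"] == cls) & np.array(
                    [window_of(s) == label for s in starts]
                )
                depths = labelled.loc[sel, "max_depth_um"].to_numpy()
            rows.append(
                {
                    "window": label,
                    "label": cls,
                    "n": int(depths.size),
                    "mean_max_depth_um": float(depths.mean()) if depths.size else np.nan,
                    "sd_max_depth_um": float(depths.std(ddof=0)) if depths.size else np.nan,
                    "furrow_depth_um": furrow_mean,
                }
            )
    return pd.DataFrame(rows)
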