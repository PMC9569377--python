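"""Linking per-frame localizations into tracks; region assignment; TALM maps.

Detections (frame index plus x, y in µm) are linked frame-to-frame by a
greedy mutual-nearest-neighbour rule within a tracking radius.  One missing
frame may be bridged if the molecule was already detected for a minimum
number of consecutive frames before the gap.  Tracks are assigned to
annotated regions only when they lie completely inside one polygon;
border-crossing tracks are discarded.  TALM (tracking-and-localization
microscopy) maps are binned localization-count rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.prepared import prep

from .geometry import Region

__all__ = [
    "TrackingConfig",
    "Track",
    "BOUND_TRACKING_PRESETS",
    "link_nearest_neighbor",
    "assign_tracks_to_regions",
    "talm_map",
    "predict_tracking_radius",
    "tracks_to_dataframe",
]

#: Camera pixel size of the imaging system (µm); metadata for TALM binning.
CAMERA_PIXEL_UM = 0.166

#: Bound-molecule tracking presets per frame cycle time: radius (µm) and
#: minimum track length (frames).  Radii follow the published loss-probability
#: prediction for each condition.
BOUND_TRACKING_PRESETS = {
    0.0117: {"radius": 0.257, "min_track_length": 5},
    0.058: {"radius": 0.340, "min_track_length": 3},
    0.199: {"radius": 0.485, "min_track_length": 3},
    1.006: {"radius": 0.601, "min_track_length": 3},
}


@dataclass
class TrackingConfig:
    """Nearest-neighbour linking parameters."""

    radius: float = 1.66  # µm (10 camera pixels)
    gap_frames: int = 1
    min_frames_before_gap: int = 2
    min_track_length: int = 2  # frames; shorter tracks are demoted
    frame_cycle_time: float = 0.0117  # s

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.gap_frames < 0 or self.min_frames_before_gap < 1:
            raise ValueError("invalid gap settings")

    @classmethod
    def bound_preset(cls, frame_cycle_time: float) -> "TrackingConfig":
        """Preset for tracking bound molecules at a given cycle time."""
        preset = BOUND_TRACKING_PRESETS.get(round(frame_cycle_time, 4))
        if preset is None:
            raise KeyError(f"no bound-tracking preset for {frame_cycle_time} s")
        return cls(
            radius=preset["radius"],
            min_track_length=preset["min_track_length"],
            frame_cycle_time=frame_cycle_time,
        )


@dataclass
class Track:
    """An ordered sequence of linked detections."""

    frames: np.ndarray  # strictly increasing frame indices
    xy: np.ndarray  # (n, 2) µm
    region_label: str = "unassigned"  # interface|cavity|unassigned|discarded
    gaps: list[int] = field(default_factory=list)  # frame indices bridged
    detection_ids: np.ndarray | None = None  # rows of the input table

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and coordinates must align")
        if len(self.frames) > 1 and not (np.diff(self.frames) > 0).all():
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_frames(self) -> int:
        return int(self.frames[-1] - self.frames[0]) if len(self) else 0


def _as_detection_table(detections) -> pd.DataFrame:
    df = pd.DataFrame(detections)
    required = {"frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection table lacks columns {sorted(missing)}")
    return df.sort_values("frame", kind="stable").reset_index(drop=False)


def link_nearest_neighbor(
    detections, config: TrackingConfig | None = None
) -> tuple[list[Track], pd.DataFrame]:
    """Link detections into tracks by greedy global-nearest assignment.

    Within each frame transition, all candidate (track head, detection)
    pairs closer than the radius are sorted by distance and accepted
    greedily, so the closest pairs win conflicts.  A track already detected
    in at least ``min_frames_before_gap`` consecutive frames may bridge up
    to ``gap_frames`` missing frames; the same radius applies across a gap.
    Tracks shorter than ``min_track_length`` are demoted to unlinked
    detections.

    Returns ``(tracks, unlinked)`` where ``unlinked`` is the sub-table of
    detections that ended up in no track.
    """
    if config is None:
        config = TrackingConfig()
    df = _as_detection_table(detections)
    if df.empty:
        return [], df

    class _Builder:
        __slots__ = ("rows", "frames", "xy", "run", "gaps")

        def __init__(self, row, frame, xy):
            self.rows = [row]
            self.frames = [frame]
            self.xy = [xy]
            self.run = 1  # consecutive-frame streak
            self.gaps: list[int] = []

        def extend(self, row, frame, xy):
            gap = frame - self.frames[-1] - 1
            if gap > 0:
                self.gaps.extend(range(self.frames[-1] + 1, frame))
                self.run = 1
            else:
                self.run += 1
            self.rows.append(row)
            self.frames.append(frame)
            self.xy.append(xy)

    open_tracks: list[_Builder] = []
    done: list[_Builder] = []
    frames = df["frame"].to_numpy()
    coords = df[["x_um", "y_um"]].to_numpy()
    order = df["index"].to_numpy()  # original row ids

    for frame in np.unique(frames):
        sel = np.nonzero(frames == frame)[0]
        pts = coords[sel]
        # retire tracks that can no longer be extended
        still_open = []
        for tr in open_tracks:
            age = frame - tr.frames[-1]
            allowed = 1 + (config.gap_frames if tr.run >= config.min_frames_before_gap else 0)
            if age > allowed:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        assigned_det = np.zeros(len(sel), dtype=bool)
        if open_tracks and len(sel):
            heads = np.array([tr.xy[-1] for tr in open_tracks])
            d = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=2)
            ti, di = np.nonzero(d <= config.radius)
            for idx in np.argsort(d[ti, di], kind="stable"):
                t, j = ti[idx], di[idx]
                tr = open_tracks[t]
                if assigned_det[j] or tr.frames[-1] == frame:
                    continue
                tr.extend(order[sel[j]], int(frame), pts[j])
                assigned_det[j] = True
        for j in np.nonzero(~assigned_det)[0]:
            open_tracks.append(_Builder(order[sel[j]], int(frame), pts[j]))

    done.extend(open_tracks)

    tracks: list[Track] = []
    unlinked_rows: list[int] = []
    for tr in done:
        if len(tr.frames) >= max(config.min_track_length, 2):
            tracks.append(
                Track(
                    frames=np.array(tr.frames),
                    xy=np.array(tr.xy),
                    gaps=tr.gaps,
                    detection_ids=np.array(tr.rows),
                )
            )
        else:
            unlinked_rows.extend(tr.rows)
    unlinked = (
        df.set_index("index").loc[sorted(unlinked_rows)].reset_index()
        if unlinked_rows
        else df.iloc[0:0]
    )
    return tracks, unlinked


def assign_tracks_to_regions(
    tracks: list[Track], regions: list[Region]
) -> list[Track]:
    """Label tracks by the region polygons they lie in, in place.

    A track gets a region class only if every localization falls inside a
    single polygon; tracks crossing a polygon border are ``discarded``
    (they would mix statistics of different compartments) and tracks
    entirely outside all polygons stay ``unassigned``.
    """
    prepared = [(r.label, prep(r.polygon), r.polygon) for r in regions]
    for track in tracks:
        x, y = track.xy[:, 0], track.xy[:, 1]
        inside_any = np.zeros(len(track), dtype=bool)
        label = None
        for region_label, prepared_poly, poly in prepared:
            inside = contains_xy(poly, x, y)
            if inside.all():
                label = region_label
                break
            inside_any |= inside
        if label is not None:
            track.region_label = label
        elif inside_any.any():
            track.region_label = "discarded"
        else:
            track.region_label = "unassigned"
    return tracks


def talm_map(
    detections,
    bin_px: int = 2,
    pixel_size_um: float = CAMERA_PIXEL_UM,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Localization-count raster with ``bin_px`` camera pixels per bin.

    Accepts a detection table or a list of tracks.  The raster sums to the
    number of localizations.
    """
    if bin_px < 1:
        raise ValueError("bin_px must be >= 1")
    if isinstance(detections, list):  # tracks
        if detections:
            xy = np.vstack([t.xy for t in detections])
        else:
            xy = np.empty((0, 2))
    else:
        df = pd.DataFrame(detections)
        xy = df[["x_um", "y_um"]].to_numpy()
    bin_um = bin_px * pixel_size_um
    if shape is None:
        if len(xy) == 0:
            return np.zeros((1, 1), dtype=np.int64)
        shape = (
            int(np.floor(xy[:, 1].max() / bin_um)) + 1,
            int(np.floor(xy[:, 0].max() / bin_um)) + 1,
        )
    raster = np.zeros(shape, dtype=np.int64)
    cols = np.clip((xy[:, 0] / bin_um).astype(int), 0, shape[1] - 1)
    rows = np.clip((xy[:, 1] / bin_um).astype(int), 0, shape[0] - 1)
    np.add.at(raster, (rows, cols), 1)
    return raster


def predict_tracking_radius(
    D_fast: float, frame_cycle_time: float, loss_probability: float = 0.005
) -> float:
    """Radius at which a free jump escapes with the given probability.

    For 2D diffusion the jump exceeds r with probability
    ``exp(-r²/(4 D t))``; setting this to the loss probability gives
    ``r = sqrt(-4 D t ln(p))``.  This captures the intent of matching
    tracking-loss probabilities across time-lapse conditions; published
    preset radii additionally fold in photobleaching and are therefore kept
    as constants (:data:`BOUND_TRACKING_PRESETS`) rather than recomputed.
    """
    if not 0 < loss_probability < 1:
        raise ValueError("loss_probability must be in (0, 1)")
    if D_fast <= 0 or frame_cycle_time <= 0:
        raise ValueError("D_fast and frame_cycle_time must be positive")
    return float(np.sqrt(-4.0 * D_fast * frame_cycle_time * np.log(loss_probability)))


def tracks_to_dataframe(
    tracks: list[Track], frame_cycle_time: float = 0.0117
) -> pd.DataFrame:
    """Long-format track table (track_id, frame, t_s, x_um, y_um, region...)."""
    rows = []
    for tid, tr in enumerate(tracks):
        for frame, (x, y) in zip(tr.frames, tr.xy):
            rows.append(
                (
                    tid,
                    int(frame),
                    frame * frame_cycle_time,
                    x,
                    y,
                    tr.region_label,
                    frame in tr.gaps,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "frame",
            "t_s",
            "x_um",
            "y_um",
            "region_label",
            "gap_flag",
        ],
    )
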