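"""Jump-angle anisotropy and MSD-based diffusion estimates.

The angle θ between two consecutive jumps of a track reports on confinement:
free Brownian motion is isotropic (flat angle distribution) while motion in
a narrow channel or near a binding site over-represents reversals
(θ ≈ 180°).  The fold anisotropy f180/0 compares the probability of
backward wedges (180° ± 30°) to forward wedges (0° ± 30°).

For bound molecules the diffusion coefficient is estimated from the first
10 points of the time-averaged mean squared displacement, fitted with
``MSD = 4 D τ + c`` where c absorbs the localization error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .tracking import Track

__all__ = [
    "AngleSample",
    "MsdResult",
    "jump_angles",
    "fold_anisotropy",
    "angle_to_border",
    "msd_fit",
    "msd_curve",
]

#: Minimum jump length (µm) for both segments of an angle: 1 camera pixel.
MIN_JUMP_UM = 0.166

#: MSD fits above this diffusion coefficient are flagged (µm²/s).
MSD_DISCARD_THRESHOLD = 0.5


@dataclass
class AngleSample:
    """Direction changes θ in degrees, [0, 360)."""

    angles: np.ndarray
    min_jump: float = MIN_JUMP_UM
    region: str = "all"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float) % 360.0

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    def histogram(self, bin_deg: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(0.0, 360.0 + bin_deg / 2, bin_deg)
        counts, _ = np.histogram(self.angles, bins=edges)
        return edges, counts


@dataclass
class MsdResult:
    """Linear MSD fit of one track."""

    D: float  # µm²/s
    intercept: float  # µm²; ~4 ε² for a stationary track with noise ε
    n_points_fit: int
    track_length: int  # frames
    discarded: bool  # True when D exceeds the bound-molecule ceiling


def jump_angles(
    tracks: list[Track],
    min_jump: float = MIN_JUMP_UM,
    region: str | None = None,
) -> AngleSample:
    """Angles between consecutive jumps (three consecutive localizations).

    θ = 0° is straight ahead, 180° a full reversal; angles below 180° turn
    right, above 180° left.  Both jumps must be consecutive-frame moves (no
    bridged gap in between) and at least ``min_jump`` long.
    """
    collected = []
    for tr in tracks:
        if region is not None and tr.region_label != region:
            continue
        if len(tr) < 3:
            continue
        v = np.diff(tr.xy, axis=0)
        consecutive = np.diff(tr.frames) == 1
        lengths = np.linalg.norm(v, axis=1)
        for i in range(len(v) - 1):
            if not (consecutive[i] and consecutive[i + 1]):
                continue
            if lengths[i] < min_jump or lengths[i + 1] < min_jump:
                continue
            cross = v[i, 0] * v[i + 1, 1] - v[i, 1] * v[i + 1, 0]
            dot = float(v[i] @ v[i + 1])
            theta = np.degrees(np.arctan2(cross, dot)) % 360.0
            collected.append(theta)
    return AngleSample(
        angles=np.asarray(collected), min_jump=min_jump, region=region or "all"
    )


def fold_anisotropy(sample: AngleSample, wedge_deg: float = 30.0) -> float:
    """f180/0: probability of backward vs forward wedges.

    Backward: θ in 180° ± wedge; forward: θ within wedge of 0°.  Returns
    ``inf`` (with a warning) when the forward wedge is empty but the
    backward one is not; raises if both are empty.
    """
    theta = sample.angles
    if theta.size == 0:
        raise ValueError("no angles in sample")
    backward = ((theta >= 180.0 - wedge_deg) & (theta <= 180.0 + wedge_deg)).sum()
    forward = ((theta <= wedge_deg) | (theta >= 360.0 - wedge_deg)).sum()
    if forward == 0:
        if backward == 0:
            raise ValueError("no angles in either wedge")
        warnings.warn("empty forward wedge; fold anisotropy undefined", stacklevel=2)
        return float("inf")
    return float(backward / forward)


def angle_to_border(jump: np.ndarray, region_polygon: Polygon) -> float:
    """Acute angle (degrees) between a jump and the local region border.

    The border direction is taken at the polygon vertex closest to the
    jump's midpoint (ties broken by lowest vertex index) as the average of
    the two adjacent edge directions; edges are averaged as undirected
    lines.  0° means the jump runs along the border, 90° perpendicular to
    it.
    """
    jump = np.asarray(jump, dtype=float).reshape(2, 2)
    verts = np.asarray(region_polygon.exterior.coords)
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    edge_lengths = np.linalg.norm(np.diff(np.vstack([verts, verts[:1]]), axis=0), axis=1)
    if (edge_lengths == 0).any():
        raise ValueError("polygon has zero-length edges")
    midpoint = jump.mean(axis=0)
    d2 = ((verts - midpoint) ** 2).sum(axis=1)
    i = int(np.argmin(d2))  # argmin takes the lowest index on ties
    prev_v = verts[(i - 1) % len(verts)]
    next_v = verts[(i + 1) % len(verts)]
    e1 = verts[i] - prev_v
    e2 = next_v - verts[i]
    # undirected average: flip the second edge if it opposes the first
    if e1 @ e2 < 0:
        e2 = -e2
    border = e1 / np.linalg.norm(e1) + e2 / np.linalg.norm(e2)
    norm = np.linalg.norm(border)
    if norm == 0:  # exactly anti-parallel edges (degenerate corner)
        border = e1
        norm = np.linalg.norm(e1)
    border /= norm
    v = jump[1] - jump[0]
    vnorm = np.linalg.norm(v)
    if vnorm == 0:
        raise ValueError("zero-length jump")
    cosang = abs(float(v @ border)) / vnorm
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def msd_curve(track: Track, max_lag: int = 10) -> np.ndarray:
    """Time-averaged MSD at lags 1..max_lag using all overlapping pairs.

    Pairs are indexed by frame difference, so bridged gaps simply do not
    contribute pairs at the affected lags.
    """
    frames = track.frames
    xy = track.xy
    out = np.full(max_lag, np.nan)
    frame_index = {int(f): i for i, f in enumerate(frames)}
    for lag in range(1, max_lag + 1):
        sq = [
            ((xy[frame_index[f + lag]] - xy[i]) ** 2).sum()
            for i, f in enumerate(frames)
            if (f + lag) in frame_index
        ]
        if sq:
            out[lag - 1] = float(np.mean(sq))
    return out


def msd_fit(
    track: Track,
    frame_cycle_time: float = 0.0117,
    n_points: int = 10,
    min_frames: int = 20,
    discard_above: float = MSD_DISCARD_THRESHOLD,
) -> MsdResult:
    """Linear fit of the first ``n_points`` MSD lags: MSD = 4 D τ + c.

    Only tracks of at least ``min_frames`` frames qualify.  Results with
    D above ``discard_above`` are flagged as discarded (too fast to be a
    bound molecule) but still returned.
    """
    if len(track) < min_frames:
        raise ValueError(f"track shorter than {min_frames} frames")
    msd = msd_curve(track, max_lag=n_points)
    lags = np.arange(1, n_points + 1) * frame_cycle_time
    ok = ~np.isnan(msd)
    if ok.sum() < 2:
        raise ValueError("not enough MSD points to fit")
    slope, intercept = np.polyfit(lags[ok], msd[ok], 1)
    d = float(slope / 4.0)
    return MsdResult(
        D=d,
        intercept=float(intercept),
        n_points_fit=int(ok.sum()),
        track_length=len(track),
        discarded=d > discard_above,
    )
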