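"""Nucleus segmentation, tracking and kinematics.

Nuclei are segmented per frame from the (max z-projected) nuclear
channel by Gaussian smoothing, Otsu thresholding, hole filling and a
minimum-area filter; they are then linked frame-to-frame by greedy
nearest-neighbour matching under a maximum jump distance.  For every
track the per-frame velocity vector, speed and movement direction are
computed by forward differences, and the track persistence is the net
displacement divided by the path length.  The per-frame movement
direction defines the velocity-relative polar frame used by the angular
statistics; frames that move less than a minimum displacement are
flagged direction-undefined and excluded from that analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .errors import SampleSizeError, ValidationError
from .geometry import vector_angle_deg

log = logging.getLogger(__name__)

__all__ = ["NucleusTrack", "segment_nuclei", "track_nuclei", "compute_kinematics"]


@dataclass
class NucleusTrack:
    """One nucleus followed over time.

    Centroids are physical ``(x, y)`` positions in micrometres.  After
    :func:`compute_kinematics` the per-frame velocity (forward
    difference), speed and direction are filled in; the direction of the
    last frame (and of frames below the minimum-displacement gate) is
    NaN.
    """

    track_id: int
    frames: np.ndarray
    centroids_um: np.ndarray
    labels: np.ndarray
    velocities_um_min: np.ndarray | None = None
    speeds_um_min: np.ndarray | None = None
    directions_deg: np.ndarray | None = None
    persistence: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError("track frames must be strictly increasing")
        if self.centroids_um.shape != (self.frames.size, 2):
            raise ValidationError("centroids must be (n_frames, 2)")

    def __len__(self) -> int:
        return self.frames.size

    def as_table(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "track_id": np.full(n, self.track_id),
                "frame": self.frames,
                "x_um": self.centroids_um[:, 0],
                "y_um": self.centroids_um[:, 1],
                "speed_um_min": self.speeds_um_min
                if self.speeds_um_min is not None
                else np.full(n, np.nan),
                "direction_deg": self.directions_deg
                if self.directions_deg is not None
                else np.full(n, np.nan),
                "persistence": np.full(
                    n, self.persistence if self.persistence is not None else np.nan
                ),
            }
        )


def segment_nuclei(
    frame: np.ndarray,
    nucleus_radius_px: float,
    smooth_sigma_px: float | None = None,
    min_area_px: float | None = None,
) -> np.ndarray:
    """Segment nuclei in a 2-D image (max z-projection of the nuclear channel).

    Gaussian smoothing (default sigma = nucleus radius / 4), Otsu
    threshold, hole filling and a minimum-area filter (default 25% of
    the expected nucleus area).  Returns a labeled mask with labels
    ordered by descending region area; an all-background image yields an
    all-zero labeling rather than an error.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError(f"expected a 2-D frame, got ndim={frame.ndim}")
    if smooth_sigma_px is None:
        smooth_sigma_px = nucleus_radius_px / 4.0
    if min_area_px is None:
        min_area_px = 0.25 * np.pi * nucleus_radius_px**2
    smoothed = ndimage.gaussian_filter(frame, smooth_sigma_px)
    if smoothed.max() <= smoothed.min():
        return np.zeros(frame.shape, dtype=np.int32)
    thr = filters.threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(smoothed > thr)
    labeled, _ = ndimage.label(binary)
    regions = measure.regionprops(labeled)
    keep = [r for r in regions if r.area >= min_area_px]
    keep.sort(key=lambda r: -r.area)
    out = np.zeros(frame.shape, dtype=np.int32)
    for new_label, r in enumerate(keep, start=1):
        out[labeled == r.label] = new_label
    return out


def _frame_centroids(labeled: np.ndarray, pixel_size: float) -> pd.DataFrame:
    regions = measure.regionprops(labeled)
    return pd.DataFrame(
        {
            "label": [r.label for r in regions],
            "x_um": [r.centroid[1] * pixel_size for r in regions],
            "y_um": [r.centroid[0] * pixel_size for r in regions],
        }
    )


def track_nuclei(
    labeled_frames: list[np.ndarray] | np.ndarray,
    pixel_size: float,
    max_jump_um: float,
) -> list[NucleusTrack]:
    """Link per-frame nucleus detections into tracks.

    Greedy nearest-neighbour linking: candidate (track-end, detection)
    pairs at consecutive frames are accepted in order of increasing
    distance, subject to the *max_jump_um* gate; ties are broken toward
    the smaller detection label, so the procedure is deterministic.
    Unmatched detections open new tracks; unmatched tracks end.
    """
    per_frame = [_frame_centroids(np.asarray(lf), pixel_size) for lf in labeled_frames]

    tracks: list[dict] = []  # each: {'frames': [], 'centroids': [], 'labels': []}

    def _new_track(frame_idx: int, row) -> None:
        tracks.append(
            {
                "frames": [frame_idx],
                "centroids": [(row.x_um, row.y_um)],
                "labels": [int(row.label)],
            }
        )

    prev_assignment: dict[int, int] = {}  # detection row -> track index
    for frame_idx, table in enumerate(per_frame):
        if frame_idx == 0:
            for i, row in enumerate(table.itertuples(index=False)):
                _new_track(frame_idx, row)
                prev_assignment[i] = i
            continue
        prev_table = per_frame[frame_idx - 1]
        candidates = []
        for ti, pi in prev_assignment.items():
            px, py = prev_table.x_um.iloc[ti], prev_table.y_um.iloc[ti]
            for j, row in enumerate(table.itertuples(index=False)):
                d = float(np.hypot(row.x_um - px, row.y_um - py))
                if d <= max_jump_um:
                    candidates.append((d, int(row.label), pi, j))
        candidates.sort()  # distance first, then smaller label
        new_assignment: dict[int, int] = {}
        used_tracks: set[int] = set()
        used_detections: set[int] = set()
        for _d, _lbl, track_idx, det_idx in candidates:
            if track_idx in used_tracks or det_idx in used_detections:
                continue
            used_tracks.add(track_idx)
            used_detections.add(det_idx)
            row = table.iloc[det_idx]
            tracks[track_idx]["frames"].append(frame_idx)
            tracks[track_idx]["centroids"].append((row.x_um, row.y_um))
            tracks[track_idx]["labels"].append(int(row.label))
            new_assignment[det_idx] = track_idx
        for j, row in enumerate(table.itertuples(index=False)):
            if j not in used_detections:
                _new_track(frame_idx, row)
                new_assignment[j] = len(tracks) - 1
        # remap: prev_assignment keys are detection rows of current frame
        prev_assignment = {det: trk for det, trk in new_assignment.items()}

    out = []
    for tid, t in enumerate(tracks):
        out.append(
            NucleusTrack(
                track_id=tid,
                frames=np.array(t["frames"]),
                centroids_um=np.array(t["centroids"]),
                labels=np.array(t["labels"]),
            )
        )
    return out


def compute_kinematics(
    track: NucleusTrack,
    frame_interval_min: float,
    min_displacement_um: float = 0.0,
) -> NucleusTrack:
    """Fill per-frame velocity, speed, direction and track persistence.

    Velocity at frame ``t`` is the forward difference
    ``(c[t+1] - c[t]) / frame_interval`` so that the direction at frame
    ``t`` describes the step the nucleus is taking; the last frame has
    no defined velocity.  Frames whose displacement is below
    *min_displacement_um* keep their speed but have direction NaN (the
    velocity frame is meaningless for a stalled nucleus).  Persistence
    is net displacement over path length, in [0, 1].
    """
    n = len(track)
    if n < 2:
        raise SampleSizeError("kinematics need a track with >= 2 frames")
    steps = np.diff(track.centroids_um, axis=0)
    dt = np.diff(track.frames) * frame_interval_min
    velocities = np.full((n, 2), np.nan)
    velocities[:-1] = steps / dt[:, None]
    speeds = np.full(n, np.nan)
    step_norms = np.linalg.norm(steps, axis=1)
    speeds[:-1] = step_norms / dt
    directions = np.full(n, np.nan)
    defined = step_norms >= max(min_displacement_um, 1e-12)
    directions[:-1][defined] = vector_angle_deg(
        steps[defined, 0], steps[defined, 1]
    )
    path_length = float(step_norms.sum())
    net = float(np.linalg.norm(track.centroids_um[-1] - track.centroids_um[0]))
    persistence = net / path_length if path_length > 0 else 0.0
    track.velocities_um_min = velocities
    track.speeds_um_min = speeds
    track.directions_deg = directions
    track.persistence = min(persistence, 1.0)
    return track


def tracks_table(tracks: list[NucleusTrack]) -> pd.DataFrame:
    """Concatenate tracks into one tidy table (one row per track-frame)."""
    if not tracks:
        return pd.DataFrame(
            columns=[
                "track_id",
                "frame",
                "x_um",
                "y_um",
                "speed_um_min",
                "direction_deg",
                "persistence",
            ]
        )
    return pd.concat([t.as_table() for t in tracks], ignore_index=True)
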