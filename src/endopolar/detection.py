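"""Endosome spot detection and assignment to nuclei.

Spots are detected per frame on the (max z-projected) endosome channel
by scale-normalized Laplacian-of-Gaussian enhancement, a robust
response threshold, regional maxima as markers, and marker-controlled
watershed on the inverted response restricted to the above-threshold
support.  The watershed step splits touching spots that a plain
connected-component analysis would merge.  Detected spots are then
assigned to the nearest tracked nucleus within a maximum radius.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["detect_endosomes", "assign_spots_to_nucleus", "log_response"]

SPOT_COLUMNS = ["frame", "x_um", "y_um", "response", "area_px"]


def log_response(frame: np.ndarray, spot_sigma_px: float) -> np.ndarray:
    """Scale-normalized, sign-flipped LoG response (bright spots positive)."""
    frame = np.asarray(frame, dtype=float)
    return -(spot_sigma_px**2) * ndimage.gaussian_laplace(frame, spot_sigma_px)


def _robust_threshold(response: np.ndarray, k: float) -> float:
    """Median + k robust standard deviations (1.4826 * MAD) of the response.

    Both the median and the MAD scale linearly with the image intensity,
    so detection is invariant to a global intensity scale factor.
    """
    med = float(np.median(response))
    mad = float(np.median(np.abs(response - med)))
    return med + k * 1.4826 * mad


def detect_endosomes(
    frame: np.ndarray,
    spot_sigma_px: float,
    pixel_size: float,
    threshold_k: float = 5.0,
    threshold: float | None = None,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Detect spot centroids in a 2-D frame.

    Parameters
    ----------
    frame
        2-D intensity image.
    spot_sigma_px
        Expected spot scale in pixels (the LoG sigma).
    pixel_size
        Micrometres per pixel, used to report physical centroids.
    threshold_k
        Robust-SD multiplier for the automatic response threshold.
    threshold
        Absolute response threshold overriding the automatic one.
    frame_index
        Value written to the ``frame`` column of the output.

    Returns
    -------
    DataFrame with columns ``frame, x_um, y_um, response, area_px``;
    the centroid is the intensity-weighted center of each watershed
    basin.  A blank frame yields an empty table.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError(f"expected a 2-D frame, got ndim={frame.ndim}")
    if not spot_sigma_px > 0:
        raise ValidationError("spot_sigma_px must be > 0")
    response = log_response(frame, spot_sigma_px)
    if threshold is None:
        if response.max() <= response.min():
            return pd.DataFrame(columns=SPOT_COLUMNS)
        threshold = _robust_threshold(response, threshold_k)
    support = response > threshold
    if not support.any():
        return pd.DataFrame(columns=SPOT_COLUMNS)
    # regional maxima (8-connectivity); a plateau forms a single marker
    maxima = morphology.local_maxima(response, connectivity=2) & support
    markers, n_markers = ndimage.label(maxima, structure=np.ones((3, 3)))
    if n_markers == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    basins = segmentation.watershed(-response, markers=markers, mask=support, connectivity=2)
    regions = measure.regionprops(basins, intensity_image=frame)
    rows = []
    for r in regions:
        cy, cx = r.centroid_weighted
        rows.append(
            (
                frame_index,
                cx * pixel_size,
                cy * pixel_size,
                float(response[basins == r.label].max()),
                int(r.area),
            )
        )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def detect_endosomes_movie(
    frames: np.ndarray,
    spot_sigma_px: float,
    pixel_size: float,
    threshold_k: float = 5.0,
) -> pd.DataFrame:
    """Run :func:`detect_endosomes` on every frame of a (T, Y, X) array."""
    tables = [
        detect_endosomes(
            frames[t], spot_sigma_px, pixel_size, threshold_k=threshold_k, frame_index=t
        )
        for t in range(frames.shape[0])
    ]
    tables = [t for t in tables if len(t)]
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=SPOT_COLUMNS)


def assign_spots_to_nucleus(
    spots: pd.DataFrame,
    tracks,
    max_radius_um: float,
) -> pd.DataFrame:
    """Assign each spot to the nearest nucleus centroid within *max_radius_um*.

    *tracks* is a sequence of :class:`~endopolar.tracking.NucleusTrack`.
    Spots with no nucleus within the radius are dropped; the count is
    logged.  Returns the spot table with a ``track_id`` column added.
    """
    rows = []
    n_dropped = 0
    # index: frame -> list of (track_id, x, y)
    frame_index: dict[int, list[tuple[int, float, float]]] = {}
    for t in tracks:
        for i, f in enumerate(t.frames):
            frame_index.setdefault(int(f), []).append(
                (t.track_id, t.centroids_um[i, 0], t.centroids_um[i, 1])
            )
    for spot in spots.itertuples(index=False):
        nuclei = frame_index.get(int(spot.frame), [])
        best = None
        best_d = np.inf
        for tid, x, y in nuclei:
            d = np.hypot(spot.x_um - x, spot.y_um - y)
            if d < best_d:
                best_d, best = d, tid
        if best is None or best_d > max_radius_um:
            n_dropped += 1
            continue
        rows.append((*spot, best))
    if n_dropped:
        log.info("assign_spots_to_nucleus: dropped %d unassigned spots", n_dropped)
    return pd.DataFrame(rows, columns=list(spots.columns) + ["track_id"])
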