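"""Ground-truthed synthetic microscopy scenes.

The raw movies behind the confined-migration measurements are not
publicly deposited, so this module generates synthetic data with the
same statistical structure the downstream analysis assumes:

* nuclei performing a persistent random walk at a set speed, rendered as
  filled ellipses (or two-lobed "peanut" shapes for deformed nuclei);
* endosome point clouds whose angles relative to the instantaneous
  movement direction follow a von Mises / uniform mixture with
  controllable concentration;
* a centrosome placed ahead of or behind the nucleus front with a
  controllable per-frame Bernoulli probability;
* degradation-spot fields of controllable density;
* line-scan intensity fields with an anterior-to-nucleus bump;
* Gaussian PSF blur plus Poisson and Gaussian camera noise on 16-bit
  images with a constant background offset.

Every generated quantity is recorded as ground truth, so detection,
tracking and statistics can be scored against the exact values used to
render the pixels.  Identical parameters and seed reproduce identical
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptySampleError, ParameterError
from .geometry import unit_from_angle_deg, vector_angle_deg, wrap_deg
from .io import ImageStack

log = logging.getLogger(__name__)

__all__ = [
    "SceneParams",
    "GroundTruth",
    "generate_scene",
    "render_movie",
    "sample_angles",
    "generate_nucleus_population",
    "generate_degradation_field",
    "generate_linescan_scene",
]

BACKGROUND_OFFSET = 100.0
NUCLEUS_AMPLITUDE = 800.0
ENDOSOME_AMPLITUDE = 600.0
DEGRADATION_AMPLITUDE = 600.0
CENTROSOME_OFFSET_AHEAD = 1.5  # x nucleus radius, beyond the front edge
CENTROSOME_OFFSET_BEHIND = 0.35  # x nucleus radius, inside the mask
PEANUT_LOBE_RATIO = 0.75  # lobe radius / nominal nucleus radius
PEANUT_SEPARATION = 1.8  # lobe-center separation / lobe radius
PSF_SIGMA_PX = 0.8


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic migration scene.

    Defaults describe the confined control regime: nuclei of ~8 um
    radius imaged every 5 minutes at 0.5 um/pixel, moving ~0.4 um/min
    with fairly persistent directionality, and endosome angles drawn
    from a von Mises mixture about the movement direction.  The von
    Mises concentration for a desired front-quadrant mass can be
    obtained with :func:`endopolar.circular.kappa_for_front_fraction`.
    """

    n_cells: int = 5
    n_frames: int = 30
    frame_interval: float = 5.0  # min
    pixel_size: float = 0.5  # um / pixel
    image_shape: tuple[int, int] = (768, 768)  # rows, cols
    nucleus_radius: float = 8.0  # um
    speed_mean: float = 0.4  # um / min
    turn_persistence: float = 0.7  # 1 = straight line
    turn_sd_deg: float = 90.0  # base SD of the direction update
    endosome_count_per_cell: int = 12
    angular_mixture: tuple[float, float, float] = (1.0, 0.0, 2.0)  # weight, mu, kappa
    endosome_radius_range: tuple[float, float] = (4.0, 20.0)  # um
    centrosome_ahead_prob: float = 0.5
    deformed_fraction: float = 0.28
    degradation_spot_density: float = 30.0  # spots per cell
    spot_sigma: float = 1.5  # px
    noise: tuple[float, float] = (1.0, 2.0)  # poisson_scale, gaussian_sd
    seed: int = 0

    def __post_init__(self) -> None:
        weight, _mu, kappa = self.angular_mixture
        checks = [
            (self.n_cells >= 1, "n_cells >= 1"),
            (self.n_frames >= 1, "n_frames >= 1"),
            (self.frame_interval > 0, "frame_interval > 0"),
            (self.pixel_size > 0, "pixel_size > 0"),
            (self.nucleus_radius > 0, "nucleus_radius > 0"),
            (self.speed_mean >= 0, "speed_mean >= 0"),
            (0 <= self.turn_persistence <= 1, "turn_persistence in [0,1]"),
            (self.endosome_count_per_cell >= 0, "endosome_count_per_cell >= 0"),
            (0 <= weight <= 1, "mixture weight in [0,1]"),
            (kappa >= 0, "kappa >= 0"),
            (0 < self.endosome_radius_range[0] <= self.endosome_radius_range[1],
             "endosome_radius_range increasing and positive"),
            (0 <= self.centrosome_ahead_prob <= 1, "centrosome_ahead_prob in [0,1]"),
            (0 <= self.deformed_fraction <= 1, "deformed_fraction in [0,1]"),
            (self.degradation_spot_density >= 0, "degradation_spot_density >= 0"),
            (self.spot_sigma > 0, "spot_sigma > 0"),
            (self.noise[0] >= 0 and self.noise[1] >= 0, "noise components >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(f"SceneParams requires {msg}")
        numeric = [
            self.frame_interval, self.pixel_size, self.nucleus_radius,
            self.speed_mean, self.turn_persistence, weight, kappa,
            *self.endosome_radius_range, self.centrosome_ahead_prob,
            self.deformed_fraction, self.degradation_spot_density,
            self.spot_sigma, *self.noise,
        ]
        if not np.all(np.isfinite(numeric)):
            raise ParameterError("SceneParams fields must be finite")
        margin = self._margin_um()
        h_um = self.image_shape[0] * self.pixel_size
        w_um = self.image_shape[1] * self.pixel_size
        if h_um <= 2 * margin or w_um <= 2 * margin:
            raise ParameterError(
                "image_shape too small to contain nuclei and their endosome clouds"
            )

    def _margin_um(self) -> float:
        return self.endosome_radius_range[1] + self.nucleus_radius

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius / self.pixel_size

    def with_front_fraction(self, target: float, weight: float = 1.0) -> "SceneParams":
        """Copy of the params with kappa calibrated to a front-quadrant mass."""
        from .circular import kappa_for_front_fraction

        kappa = kappa_for_front_fraction(target, weight=weight)
        _, mu, _ = self.angular_mixture
        return replace(self, angular_mixture=(weight, mu, kappa))

    @classmethod
    def from_dict(cls, cfg: dict) -> "SceneParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ParameterError(f"unknown SceneParams fields: {sorted(unknown)}")
        cfg = {
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()
        }
        return cls(**cfg)


def sample_angles(
    n: int,
    mixture: tuple[float, float, float],
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw *n* angles (degrees in [0, 360)) from the angular mixture.

    The mixture is ``weight * vonMises(mu_deg, kappa) + (1 - weight) *
    Uniform[0, 360)``.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise EmptySampleError(f"sample_angles needs n >= 1, got {n}")
    weight, mu_deg, kappa = mixture
    if not (0 <= weight <= 1 and kappa >= 0):
        raise ParameterError("mixture weight must be in [0,1] and kappa >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _sample_angles(rng, n, mixture)


def _sample_angles(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    weight, mu_deg, kappa = mixture
    from_vm = rng.random(n) < weight
    out = np.empty(n)
    n_vm = int(from_vm.sum())
    if n_vm:
        out[from_vm] = np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size=n_vm))
    n_unif = n - n_vm
    if n_unif:
        out[~from_vm] = rng.uniform(0.0, 360.0, size=n_unif)
    return wrap_deg(out)


@dataclass
class GroundTruth:
    """Everything a scene generated, at full precision.

    Positions are physical ``(x, y)`` micrometres; ``directions_deg``
    holds the true per-frame movement direction (NaN on the last frame,
    where no forward step exists).  Masks are rasterized on demand from
    the stored shape parameters, so the object stays light even for
    many frames.
    """

    params: SceneParams
    centroids_um: np.ndarray  # (n_cells, n_frames, 2)
    directions_deg: np.ndarray  # (n_cells, n_frames)
    deformed: np.ndarray  # (n_cells,) bool
    shape_orientations_deg: np.ndarray  # (n_cells,)
    endosomes: pd.DataFrame  # cell, frame, angle_deg, radius_um, x_um, y_um
    centrosomes_um: np.ndarray  # (n_cells, n_frames, 2)
    centrosome_ahead: np.ndarray  # (n_cells, n_frames) bool
    degradation_um: np.ndarray  # (n_spots, 2)

    def cell_mask(self, cell: int, frame: int) -> np.ndarray:
        """Boolean nucleus mask of one cell at one frame."""
        out = np.zeros(self.params.image_shape, dtype=bool)
        self._stamp(out, cell, frame, value=True)
        return out

    def labeled_mask(self, frame: int) -> np.ndarray:
        """Labeled nucleus mask of all cells at one frame (label = cell + 1)."""
        out = np.zeros(self.params.image_shape, dtype=np.int32)
        for cell in range(self.params.n_cells):
            self._stamp(out, cell, frame, value=cell + 1)
        return out

    def _stamp(self, out: np.ndarray, cell: int, frame: int, value) -> None:
        p = self.params
        cx, cy = self.centroids_um[cell, frame] / p.pixel_size  # px
        r = p.nucleus_radius_px
        orient = self.shape_orientations_deg[cell]
        if self.deformed[cell]:
            lobe_r = PEANUT_LOBE_RATIO * r
            half_sep = 0.5 * PEANUT_SEPARATION * lobe_r
            u = unit_from_angle_deg(orient)
            for s in (-1.0, 1.0):
                _stamp_disk(out, cx + s * half_sep * u[0], cy + s * half_sep * u[1],
                            lobe_r, value)
        else:
            _stamp_ellipse(out, cx, cy, r, axis_ratio=1.15, orientation_deg=orient,
                           value=value)

    def sidecar_table(self) -> pd.DataFrame:
        """Long-format ground-truth table (one row per object per frame)."""
        p = self.params
        rows = []
        for cell in range(p.n_cells):
            for t in range(p.n_frames):
                rows.append(
                    dict(object="nucleus", cell=cell, frame=t,
                         x_um=self.centroids_um[cell, t, 0],
                         y_um=self.centroids_um[cell, t, 1],
                         angle_deg=self.directions_deg[cell, t],
                         radius_um=p.nucleus_radius,
                         ahead=np.nan, deformed=bool(self.deformed[cell]))
                )
                rows.append(
                    dict(object="centrosome", cell=cell, frame=t,
                         x_um=self.centrosomes_um[cell, t, 0],
                         y_um=self.centrosomes_um[cell, t, 1],
                         angle_deg=np.nan, radius_um=np.nan,
                         ahead=bool(self.centrosome_ahead[cell, t]),
                         deformed=np.nan)
                )
        parts = [pd.DataFrame(rows)]
        if len(self.endosomes):
            parts.append(
                self.endosomes.assign(object="endosome", ahead=np.nan, deformed=np.nan)
            )
        if len(self.degradation_um):
            parts.append(
                pd.DataFrame(
                    dict(object="degradation", cell=-1, frame=-1,
                         x_um=self.degradation_um[:, 0],
                         y_um=self.degradation_um[:, 1],
                         angle_deg=np.nan, radius_um=np.nan,
                         ahead=np.nan, deformed=np.nan)
                )
            )
        cols = ["object", "cell", "frame", "x_um", "y_um", "angle_deg",
                "radius_um", "ahead", "deformed"]
        return pd.concat(parts, ignore_index=True)[cols]


def _stamp_disk(out: np.ndarray, cx: float, cy: float, radius: float, value) -> None:
    h, w = out.shape
    r0 = max(int(np.floor(cy - radius)) - 1, 0)
    r1 = min(int(np.ceil(cy + radius)) + 2, h)
    c0 = max(int(np.floor(cx - radius)) - 1, 0)
    c1 = min(int(np.ceil(cx + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (cc - cx) ** 2 + (rr - cy) ** 2 <= radius**2
    out[r0:r1, c0:c1][inside] = value


def _stamp_ellipse(
    out: np.ndarray, cx: float, cy: float, radius: float,
    axis_ratio: float, orientation_deg: float, value,
) -> None:
    """Area-preserving ellipse: semi-axes radius*sqrt(q) and radius/sqrt(q)."""
    a = radius * np.sqrt(axis_ratio)
    b = radius / np.sqrt(axis_ratio)
    h, w = out.shape
    rmax = max(a, b)
    r0 = max(int(np.floor(cy - rmax)) - 1, 0)
    r1 = min(int(np.ceil(cy + rmax)) + 2, h)
    c0 = max(int(np.floor(cx - rmax)) - 1, 0)
    c1 = min(int(np.ceil(cx + rmax)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    th = np.radians(orientation_deg)
    dx = cc - cx
    dy = -(rr - cy)  # image-coordinate sign convention
    xr = dx * np.cos(th) + dy * np.sin(th)
    yr = -dx * np.sin(th) + dy * np.cos(th)
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    out[r0:r1, c0:c1][inside] = value


def generate_scene(params: SceneParams) -> GroundTruth:
    """Generate the ground truth of one scene.

    Nuclei start on a jittered grid with a border margin wide enough to
    contain their endosome clouds, then follow a persistent random walk:
    the direction is updated each frame by wrapped-normal noise of
    standard deviation ``(1 - turn_persistence) * turn_sd_deg`` and the
    step length is ``speed_mean * frame_interval``.  Trajectories
    reflect at the margin so no pooling bias arises from border
    truncation.  Endosome angles (relative to the true step direction),
    centrosome ahead/behind flags and deformation labels are drawn per
    the configured mixture and Bernoulli rates.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    margin = p._margin_um()
    h_um = p.image_shape[0] * p.pixel_size
    w_um = p.image_shape[1] * p.pixel_size

    # jittered grid starting positions
    n_cols = int(np.ceil(np.sqrt(p.n_cells * w_um / h_um)))
    n_rows = int(np.ceil(p.n_cells / n_cols))
    xs = np.linspace(margin, w_um - margin, n_cols + 2)[1:-1]
    ys = np.linspace(margin, h_um - margin, n_rows + 2)[1:-1]
    grid = [(x, y) for y in ys for x in xs][: p.n_cells]
    jitter_scale = 0.5 * p.nucleus_radius

    centroids = np.zeros((p.n_cells, p.n_frames, 2))
    directions = np.full((p.n_cells, p.n_frames), np.nan)
    step_len = p.speed_mean * p.frame_interval
    turn_sd = (1.0 - p.turn_persistence) * p.turn_sd_deg

    for cell in range(p.n_cells):
        gx, gy = grid[cell]
        pos = np.array([gx, gy]) + rng.uniform(-jitter_scale, jitter_scale, 2)
        theta = rng.uniform(0.0, 360.0)
        centroids[cell, 0] = pos
        for t in range(1, p.n_frames):
            theta = theta + rng.normal(0.0, turn_sd) if turn_sd > 0 else theta
            u = unit_from_angle_deg(theta)
            new = pos + step_len * u
            # reflective borders
            for axis, (lo, hi) in enumerate([(margin, w_um - margin),
                                             (margin, h_um - margin)]):
                if new[axis] < lo:
                    new[axis] = 2 * lo - new[axis]
                elif new[axis] > hi:
                    new[axis] = 2 * hi - new[axis]
            step = new - pos
            if np.linalg.norm(step) > 0:
                theta = float(vector_angle_deg(step[0], step[1]))
                directions[cell, t - 1] = theta
            centroids[cell, t] = new
            pos = new

    deformed = rng.random(p.n_cells) < p.deformed_fraction
    orientations = rng.uniform(0.0, 180.0, p.n_cells)

    # endosomes: re-drawn each frame (the pooled analysis is identity-free)
    endo_rows = []
    rmin, rmax = p.endosome_radius_range
    for cell in range(p.n_cells):
        for t in range(p.n_frames):
            if not np.isfinite(directions[cell, t]) or p.endosome_count_per_cell == 0:
                continue
            ang = _sample_angles(rng, p.endosome_count_per_cell, p.angular_mixture)
            rad = rng.uniform(rmin, rmax, p.endosome_count_per_cell)
            abs_ang = wrap_deg(directions[cell, t] + ang)
            u = unit_from_angle_deg(abs_ang)
            pos = centroids[cell, t][None, :] + rad[:, None] * u
            for k in range(p.endosome_count_per_cell):
                endo_rows.append(
                    (cell, t, float(ang[k]), float(rad[k]),
                     float(pos[k, 0]), float(pos[k, 1]))
                )
    endosomes = pd.DataFrame(
        endo_rows, columns=["cell", "frame", "angle_deg", "radius_um", "x_um", "y_um"]
    )

    # centrosome: ahead/behind relative to the movement direction
    ahead = rng.random((p.n_cells, p.n_frames)) < p.centrosome_ahead_prob
    centrosomes = np.zeros_like(centroids)
    for cell in range(p.n_cells):
        last_dir = 0.0
        for t in range(p.n_frames):
            d = directions[cell, t]
            if np.isfinite(d):
                last_dir = d
            u = unit_from_angle_deg(last_dir)
            off = (CENTROSOME_OFFSET_AHEAD if ahead[cell, t]
                   else CENTROSOME_OFFSET_BEHIND) * p.nucleus_radius
            centrosomes[cell, t] = centroids[cell, t] + off * u

    n_spots = rng.poisson(p.degradation_spot_density * p.n_cells)
    degradation = np.column_stack(
        [
            rng.uniform(margin, w_um - margin, n_spots),
            rng.uniform(margin, h_um - margin, n_spots),
        ]
    ) if n_spots else np.empty((0, 2))

    return GroundTruth(
        params=p,
        centroids_um=centroids,
        directions_deg=directions,
        deformed=deformed,
        shape_orientations_deg=orientations,
        endosomes=endosomes,
        centrosomes_um=centrosomes,
        centrosome_ahead=ahead,
        degradation_um=degradation,
    )


def truth_tracks(truth: GroundTruth, min_displacement_um: float = 0.0) -> list:
    """Build kinematics-filled tracks directly from the ground-truth centroids.

    Bypasses segmentation/tracking for analyses that start from known
    trajectories (e.g. centrosome scoring on generated scenes).
    """
    from .tracking import NucleusTrack, compute_kinematics

    p = truth.params
    tracks = []
    for cell in range(p.n_cells):
        t = NucleusTrack(
            cell,
            np.arange(p.n_frames),
            truth.centroids_um[cell],
            np.full(p.n_frames, cell + 1),
        )
        tracks.append(compute_kinematics(t, p.frame_interval, min_displacement_um))
    return tracks


def _splat_points(
    img: np.ndarray, xs_px: np.ndarray, ys_px: np.ndarray, mass: float
) -> int:
    """Bilinearly deposit point masses; returns the number clipped away."""
    h, w = img.shape
    clipped = 0
    for x, y in zip(np.atleast_1d(xs_px), np.atleast_1d(ys_px)):
        c0, r0 = int(np.floor(x)), int(np.floor(y))
        fx, fy = x - c0, y - r0
        deposited = False
        for dr, dc, wt in (
            (0, 0, (1 - fx) * (1 - fy)),
            (0, 1, fx * (1 - fy)),
            (1, 0, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= c < w:
                img[r, c] += mass * wt
                deposited = True
        if not deposited:
            clipped += 1
    return clipped


def render_movie(
    truth: GroundTruth,
    params: SceneParams | None = None,
    channels: Sequence[str] = ("nucleus", "endosomes", "degradation"),
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a ground truth into a noisy multi-channel movie.

    Nuclei are filled shapes, endosomes and degradation spots are
    Gaussian peaks of ``spot_sigma``; each channel is blurred by a
    Gaussian PSF and corrupted by Poisson noise (photon scaling
    ``noise[0]``) plus additive Gaussian read noise (``noise[1]``) on a
    constant background offset, stored as 16-bit unsigned integers.
    Returns the stack together with the sidecar ground-truth table.
    Objects falling outside the field of view are clipped and logged.
    """
    p = params or truth.params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 7]))
    t_dim, c_dim = p.n_frames, len(channels)
    h, w = p.image_shape
    movie = np.zeros((t_dim, c_dim, h, w), dtype=np.uint16)
    poisson_scale, gaussian_sd = p.noise
    spot_mass = ENDOSOME_AMPLITUDE * 2 * np.pi * p.spot_sigma**2
    n_clipped = 0

    endo_by_frame = dict(tuple(truth.endosomes.groupby("frame"))) if len(
        truth.endosomes
    ) else {}

    for t in range(t_dim):
        for ci, ch in enumerate(channels):
            img = np.zeros((h, w), dtype=float)
            if ch == "nucleus":
                img[truth.labeled_mask(t) > 0] = NUCLEUS_AMPLITUDE
                img = ndimage.gaussian_filter(img, PSF_SIGMA_PX)
            elif ch == "endosomes":
                tbl = endo_by_frame.get(t)
                if tbl is not None and len(tbl):
                    n_clipped += _splat_points(
                        img,
                        tbl.x_um.to_numpy() / p.pixel_size,
                        tbl.y_um.to_numpy() / p.pixel_size,
                        spot_mass,
                    )
                img = ndimage.gaussian_filter(
                    img, np.hypot(p.spot_sigma, PSF_SIGMA_PX)
                )
            elif ch == "centrosome":
                n_clipped += _splat_points(
                    img,
                    truth.centrosomes_um[:, t, 0] / p.pixel_size,
                    truth.centrosomes_um[:, t, 1] / p.pixel_size,
                    spot_mass,
                )
                img = ndimage.gaussian_filter(
                    img, np.hypot(p.spot_sigma, PSF_SIGMA_PX)
                )
            elif ch == "degradation":
                if len(truth.degradation_um):
                    n_clipped += _splat_points(
                        img,
                        truth.degradation_um[:, 0] / p.pixel_size,
                        truth.degradation_um[:, 1] / p.pixel_size,
                        DEGRADATION_AMPLITUDE * 2 * np.pi * p.spot_sigma**2,
                    )
                img = ndimage.gaussian_filter(
                    img, np.hypot(p.spot_sigma, PSF_SIGMA_PX)
                )
            else:
                raise ParameterError(f"unknown channel {ch!r}")
            img = img + BACKGROUND_OFFSET
            if poisson_scale > 0:
                img = rng.poisson(img * poisson_scale) / poisson_scale
            if gaussian_sd > 0:
                img = img + rng.normal(0.0, gaussian_sd, img.shape)
            movie[t, ci] = np.clip(img, 0, 65535).astype(np.uint16)
    if n_clipped:
        log.warning("render_movie: clipped %d out-of-bounds point objects", n_clipped)
    stack = ImageStack(
        pixels=movie,
        pixel_size=p.pixel_size,
        frame_interval=p.frame_interval,
        channel_names=list(channels),
    )
    return stack, truth.sidecar_table()


def generate_nucleus_population(
    n: int,
    deformed_fraction: float,
    nucleus_radius_px: float = 16.0,
    crop_px: int = 96,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate *n* labeled nucleus masks for shape-classifier studies.

    Normal nuclei are mildly eccentric ellipses (axis ratio drawn in
    [1.0, 1.35]); deformed nuclei are two-lobed peanuts.  The population
    carries exactly ``round(n * deformed_fraction)`` deformed members in
    shuffled order, so the benchmark's ground-truth rate is the set rate
    (classifier error is measured without label-sampling noise).
    Returns the list of boolean masks and the ground-truth labels.
    """
    if n < 1:
        raise EmptySampleError("population needs n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_deformed = int(round(n * deformed_fraction))
    deformed = np.zeros(n, dtype=bool)
    deformed[:n_deformed] = True
    rng.shuffle(deformed)
    masks = []
    cx = cy = crop_px / 2.0
    for i in range(n):
        mask = np.zeros((crop_px, crop_px), dtype=bool)
        orient = rng.uniform(0.0, 180.0)
        if deformed[i]:
            lobe_r = PEANUT_LOBE_RATIO * nucleus_radius_px * rng.uniform(0.9, 1.1)
            half_sep = 0.5 * PEANUT_SEPARATION * lobe_r
            u = unit_from_angle_deg(orient)
            for s in (-1.0, 1.0):
                _stamp_disk(mask, cx + s * half_sep * u[0], cy + s * half_sep * u[1],
                            lobe_r, True)
        else:
            ratio = rng.uniform(1.0, 1.35)
            _stamp_ellipse(mask, cx, cy, nucleus_radius_px * rng.uniform(0.9, 1.1),
                           axis_ratio=ratio, orientation_deg=orient, value=True)
        masks.append(mask)
    return masks, deformed


def generate_degradation_field(
    n_cells: int,
    spot_density: float,
    image_shape: tuple[int, int] = (512, 512),
    spot_sigma_px: float = 2.0,
    noise: tuple[float, float] = (1.0, 2.0),
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one degradation-spot field.

    The number of spots is Poisson with mean ``spot_density * n_cells``;
    positions are uniform inside a margin.  Returns the 16-bit image and
    a truth dict with the spot count, coordinates (pixels) and cell
    count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = image_shape
    margin = 4 * spot_sigma_px + 2
    n_spots = int(rng.poisson(spot_density * n_cells))
    coords = np.column_stack(
        [rng.uniform(margin, w - margin, n_spots),
         rng.uniform(margin, h - margin, n_spots)]
    ) if n_spots else np.empty((0, 2))
    img = np.zeros(image_shape, dtype=float)
    if n_spots:
        _splat_points(img, coords[:, 0], coords[:, 1],
                      DEGRADATION_AMPLITUDE * 2 * np.pi * spot_sigma_px**2)
    img = ndimage.gaussian_filter(img, spot_sigma_px) + BACKGROUND_OFFSET
    poisson_scale, gaussian_sd = noise
    if poisson_scale > 0:
        img = rng.poisson(img * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    truth = {"n_spots": n_spots, "coords_px": coords, "n_cells": n_cells}
    return img, truth


def generate_linescan_scene(
    length_um: float = 60.0,
    pixel_size: float = 0.5,
    height_um: float = 20.0,
    nucleus_center_um: float = 25.0,
    nucleus_sigma_um: float = 5.0,
    cell_back_um: float = 5.0,
    cell_front_um: float = 55.0,
    bump_offset_um: float = 10.0,
    bump_sigma_um: float = 4.0,
    bump_amplitude: float = 500.0,
    noise_sd: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Render a two-channel field with an anterior degradation bump.

    The cell axis runs along +x at mid-height.  The DAPI channel is a
    Gaussian ridge centered on the nucleus; the degradation channel has
    a Gaussian bump *bump_offset_um* anterior to the nucleus center
    (between nucleus and cell front), emulating nucleo-anterior
    collagenolysis.  Returns channel images and the truth reference
    coordinates in micrometres along the axis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = int(round(length_um / pixel_size))
    h = int(round(height_um / pixel_size))
    x_um = (np.arange(w) + 0.0) * pixel_size
    y_px = np.arange(h)
    mid = h / 2.0
    ridge = np.exp(-((y_px - mid) ** 2) / (2 * (2.0 / pixel_size) ** 2))
    dapi_axis = 800.0 * np.exp(
        -((x_um - nucleus_center_um) ** 2) / (2 * nucleus_sigma_um**2)
    )
    bump_um = nucleus_center_um + bump_offset_um
    degr_axis = bump_amplitude * np.exp(-((x_um - bump_um) ** 2) / (2 * bump_sigma_um**2))
    dapi = BACKGROUND_OFFSET + ridge[:, None] * dapi_axis[None, :]
    degr = BACKGROUND_OFFSET + ridge[:, None] * degr_axis[None, :]
    if noise_sd > 0:
        dapi = dapi + rng.normal(0, noise_sd, dapi.shape)
        degr = degr + rng.normal(0, noise_sd, degr.shape)
    truth = {
        "cell_back_um": cell_back_um,
        "nucleus_center_um": nucleus_center_um,
        "cell_front_um": cell_front_um,
        "bump_um": bump_um,
        "axis_row": mid,
    }
    return {"degradation": degr, "dapi": dapi}, truth
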