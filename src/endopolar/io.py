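"""Image-stack and table input/output.

The in-memory container is :class:`ImageStack`: a ``T x C x (Z) x Y x X``
intensity array with physical calibration (micrometres per pixel,
minutes per frame).  Stacks are stored on disk as ImageJ-style
multi-page TIFFs so that pixel size and frame interval survive a round
trip and the files open correctly in Fiji.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import CalibrationError, FormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = ["ImageStack", "read_stack", "write_stack", "write_tables", "load_config"]


@dataclass
class ImageStack:
    """Multi-channel, multi-frame intensity image with calibration.

    Parameters
    ----------
    pixels
        Array of shape ``(T, C, Y, X)`` or ``(T, C, Z, Y, X)``.
    pixel_size
        Micrometres per pixel (isotropic in-plane).
    frame_interval
        Minutes between frames; ``None`` for a single time point.
    z_step
        Micrometres between z-slices for 5-D stacks.
    channel_names
        One name per channel; defaults to ``ch0 .. chN``.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float | None = None
    z_step: float | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (4, 5):
            raise ValidationError(
                f"pixels must be (T,C,Y,X) or (T,C,Z,Y,X); got ndim={self.pixels.ndim}"
            )
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval is not None and not self.frame_interval > 0:
            raise CalibrationError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 5

    def channel(self, key: int | str) -> np.ndarray:
        """Pixels of one channel, shape ``(T, (Z), Y, X)``."""
        if isinstance(key, str):
            try:
                key = self.channel_names.index(key)
            except ValueError as exc:
                raise ValidationError(f"no channel named {key!r}") from exc
        return self.pixels[:, key]

    def max_z_projection(self) -> "ImageStack":
        """Collapse the Z axis by maximum projection (identity for 4-D)."""
        if not self.has_z:
            return self
        return replace(self, pixels=self.pixels.max(axis=2), z_step=None)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write *stack* as an ImageJ-style TIFF with calibration metadata."""
    path = Path(path)
    data = stack.pixels
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    axes = "TCZYX" if stack.has_z else "TCYX"
    meta: dict = {"axes": axes, "unit": "um"}
    if stack.frame_interval is not None:
        # ImageJ finterval is in seconds
        meta["finterval"] = stack.frame_interval * 60.0
    if stack.z_step is not None:
        meta["spacing"] = stack.z_step
    meta["Labels"] = list(stack.channel_names)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata=meta,
    )
    return path


def _axes_to_tczyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Normalize a tifffile series to (T, C, [Z], Y, X)."""
    axes = axes.replace("S", "C") if "C" not in axes else axes.replace("S", "")
    keep = [a for a in axes if a in "TCZYX"]
    # squeeze axes tifffile reports that we do not model (e.g. 'I', 'Q')
    for i, a in enumerate(axes):
        if a not in "TCZYX":
            data = np.take(data, 0, axis=i - (len(axes) - data.ndim))
    order = [a for a in "TCZYX" if a in keep]
    src = {a: i for i, a in enumerate(keep)}
    data = np.transpose(data, [src[a] for a in order])
    # insert missing leading axes
    for a in "TCZ" if "Z" in keep else "TC":
        if a not in keep:
            pos = "TCZYX".index(a) if "Z" in keep else "TCYX".index(a)
            data = np.expand_dims(data, axis=pos)
    return data


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    z_step: float | None = None,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Calibration is taken from ImageJ/TIFF metadata unless overridden by
    the keyword arguments.  A missing pixel size with no override raises
    :class:`~endopolar.errors.CalibrationError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ij = tif.imagej_metadata or {}
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            meta_pixel_size = None
            # a bare TIFF carries a default 1:1 resolution tag; only trust
            # the value when a spatial unit is declared alongside it
            if res is not None and ij.get("unit"):
                num, den = res.value
                if num:
                    meta_pixel_size = den / num
            meta_interval = ij.get("finterval")
            if meta_interval is not None:
                meta_interval = float(meta_interval) / 60.0  # s -> min
            meta_spacing = ij.get("spacing")
            labels = ij.get("Labels")
    except (tifffile.TiffFileError, OSError) as exc:
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc

    if data.ndim < 2:
        raise FormatError(f"{path}: expected >=2-D image data, got ndim={data.ndim}")
    if data.ndim == 2:
        data = data[None, None]
        axes = "TCYX"
    else:
        data = _axes_to_tczyx(data, axes)

    px = pixel_size if pixel_size is not None else meta_pixel_size
    if px is None:
        raise CalibrationError(f"{path}: no pixel size in metadata and no override given")
    interval = frame_interval if frame_interval is not None else meta_interval
    zs = z_step if z_step is not None else (meta_spacing if data.ndim == 5 else None)
    names = channel_names
    if names is None and labels:
        names = list(labels)[: data.shape[1]]
    return ImageStack(
        pixels=data,
        pixel_size=float(px),
        frame_interval=interval,
        z_step=zs,
        channel_names=names or [],
    )


def write_tables(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    summary: dict | None = None,
    float_format: str = "%.6f",
) -> list[Path]:
    """Write one CSV per named table plus an optional JSON summary.

    Returns the list of files written.  An empty DataFrame still
    produces a header-only CSV so downstream manifests stay complete.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=float_format)
        written.append(p)
    if summary is not None:
        p = out_dir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, default=float) + "\n")
        written.append(p)
    log.info("wrote %d files to %s", len(written), out_dir)
    return written


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: expected a YAML mapping at top level")
    return cfg
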