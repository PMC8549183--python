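"""Image and table I/O.

The raw unit of work is an :class:`ImageVolume`: a multi-channel (optionally
multi-timepoint) confocal stack with intensities normalised to ``[0, 1]`` and
pixel-size metadata attached.  Acquisition metadata that TIFF files rarely
carry reliably (pixel size, z step, which channel is the wall stain and which
the ER/ER-body reporter) comes from a :class:`PipelineConfig`, a plain-text
(YAML) parameter file.

Conventions
-----------
* Axis order is canonicalised to ``(C, Z, Y, X)`` or ``(T, C, Z, Y, X)``.
* Intensities are divided by the maximum representable value of the native
  integer dtype (255 for 8-bit, 65535 for 16-bit), never by the observed
  maximum, so normalisation is monotone and reproducible across images.
* Pixel coordinates are 0-based with ``x = column``, ``y = row``; centroids
  are reported in pixel units and converted to micrometres only in reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageVolume",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
]

#: role names recognised in channel maps; wall and erbody are mandatory.
CHANNEL_ROLES = ("wall", "erbody", "t0")

DEFAULT_CHANNEL_ROLES = {"wall": 0, "erbody": 1, "t0": 2}


@dataclass
class ImageVolume:
    """A normalised confocal stack plus acquisition metadata.

    Parameters
    ----------
    data
        Float array indexed ``(C, Z, Y, X)`` or ``(T, C, Z, Y, X)`` with all
        intensities in ``[0, 1]``.
    pixel_size_um
        Edge length of one pixel in micrometres (isotropic in x/y).
    z_step_um
        Distance between consecutive z slices in micrometres.
    channel_roles
        Map from role (``wall``, ``erbody``, optionally ``t0``) to channel
        index.  ``wall`` and ``erbody`` must be present.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 2.0
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"data must be (C,Z,Y,X) or (T,C,Z,Y,X); got {self.data.ndim} axes"
            )
        if self.data.size == 0:
            raise ValueError("empty image volume")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0,1]; got [{lo}, {hi}]")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        n_c = self.data.shape[-4]
        roles = {k: int(v) for k, v in self.channel_roles.items() if int(v) < n_c}
        for required in ("wall", "erbody"):
            if required not in roles:
                raise ValueError(f"channel_roles must map '{required}' to a channel")
        if n_c > 1 and len(set(roles.values())) != len(roles):
            raise ValueError("channel_roles indices must be distinct")
        self.channel_roles = roles

    # -- convenience accessors -------------------------------------------
    @property
    def has_time(self) -> bool:
        return self.data.ndim == 5

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.has_time else 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[-4]

    @property
    def n_slices(self) -> int:
        return self.data.shape[-3]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def channel(self, role: str, frame: int | None = None) -> np.ndarray:
        """Return the ``(Z, Y, X)`` sub-stack for a channel role."""
        idx = self.channel_roles[role]
        if self.has_time:
            return self.data[0 if frame is None else frame, idx]
        if frame not in (None, 0):
            raise IndexError("volume has no time axis")
        return self.data[idx]

    def frame(self, t: int) -> "ImageVolume":
        """Single time point as a (C,Z,Y,X) volume."""
        if not self.has_time:
            raise IndexError("volume has no time axis")
        return ImageVolume(
            self.data[t],
            pixel_size_um=self.pixel_size_um,
            z_step_um=self.z_step_um,
            channel_roles=dict(self.channel_roles),
        )


# parameter name -> (default, validator description)
_CONFIG_FIELDS: dict[str, object] = {}


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, serialisable to/from YAML.

    Unknown keys in a config file are rejected so typos fail loudly instead
    of silently falling back to defaults.
    """

    # acquisition metadata defaults (used when the TIFF carries none)
    pixel_size_um: float = 0.65  # ~0.42 um^2 per pixel
    z_step_um: float = 2.0
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))

    # projection
    window_radius: int = 3
    smooth_radius: int = 2

    # segmentation
    threshold_window_px: int = 31
    threshold_offset: float = 0.02
    wall_smooth_sigma: float = 1.0
    erbody_quantile: float = 0.97
    min_cell_area_px: int = 5000
    min_seed_area_px: int = 200
    min_erbody_px: int = 10
    max_erbody_px: int = 2000
    min_erbody_intensity: float = 0.15
    voronoi_lambda: float = 10.0
    closing_radius: int = 2

    # features
    glcm_bins: int = 32
    glcm_scales: tuple = (1, 2)
    zernike_order: int = 12
    include_zernike: bool = False

    # multivariate
    kmeans_range: tuple = (6, 100)
    kmeans_restarts: int = 5
    permutations: int = 1000
    fdr_alpha: float = 0.05
    mda_subclasses: int = 3

    # dynamics
    max_link_um: float = 3.0
    moving_average_window: int = 3
    loess_span: float = 0.75
    dynamics_alpha: float = 0.01
    use_cosine_metric: bool = False

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_window_px < 3 or self.threshold_window_px % 2 == 0:
            raise ValueError("threshold_window_px must be odd and >= 3")
        if not 0 < self.erbody_quantile < 1:
            raise ValueError("erbody_quantile must be in (0,1)")
        if self.min_cell_area_px <= 0:
            raise ValueError("min_cell_area_px must be positive")
        if self.glcm_bins < 2:
            raise ValueError("glcm_bins must be >= 2")
        if any(s < 1 for s in self.glcm_scales):
            raise ValueError("glcm_scales must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0,1)")
        if self.permutations < 1:
            raise ValueError("permutations must be positive")
        lo, hi = self.kmeans_range
        if lo < 1 or hi < lo:
            raise ValueError("kmeans_range must be an increasing positive interval")
        self.glcm_scales = tuple(int(s) for s in self.glcm_scales)
        self.kmeans_range = (int(lo), int(hi))

    # -- serialisation ----------------------------------------------------
    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        unknown = sorted(set(d) - set(cls.field_names()))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        kwargs = dict(d)
        for key in ("glcm_scales", "kmeans_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glcm_scales"] = list(self.glcm_scales)
        d["kmeans_range"] = list(self.kmeans_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def _normalise(data: np.ndarray) -> np.ndarray:
    """Divide by the dtype's maximum representable value; floats pass through."""
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    out = data.astype(np.float64)
    if out.size and (out.min() < 0 or out.max() > 1):
        raise ValueError("float TIFF intensities must already lie in [0,1]")
    return out


def _resolve_axes(shape: tuple[int, ...], axes: str | None) -> str:
    """Map a TIFF array shape to an axis string over {T,C,Z,Y,X}.

    tifffile's series metadata is used when available; otherwise small
    leading axes are interpreted as C (<=4) then Z.  Ambiguity (several
    equally plausible readings) raises with the candidates listed.
    """
    if axes:
        axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
        if len(axes) == len(shape) and set(axes) <= set("TCZYX") and len(set(axes)) == len(axes):
            return axes
    ndim = len(shape)
    if ndim == 2:
        return "YX"
    if ndim == 3:
        return "CYX" if shape[0] <= 4 else "ZYX"
    if ndim == 4:
        return "CZYX" if shape[0] <= 4 else "ZCYX" if shape[1] <= 4 else _ambiguous(shape)
    if ndim == 5:
        return "TCZYX" if shape[1] <= 4 else _ambiguous(shape)
    return _ambiguous(shape)


def _ambiguous(shape: tuple[int, ...]) -> str:
    raise ValueError(
        f"cannot resolve axes of TIFF with shape {shape}: no axis metadata and "
        f"no axis small enough to be a channel axis; candidate interpretations "
        f"include CZYX, ZCYX, TZYX (supply axis metadata or reshape the file)"
    )


def read_stack(path: str | Path, config: PipelineConfig | None = None) -> ImageVolume:
    """Read a TIFF z-stack into a canonical :class:`ImageVolume`.

    Intensities are rescaled from the native bit depth to ``[0, 1]``; axis
    order is canonicalised to ``(T?)CZYX``; pixel size, z step and channel
    roles are taken from *config* when the file does not carry them.
    """
    config = config or PipelineConfig()
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = getattr(series, "axes", None)
    axes = _resolve_axes(data.shape, axes)
    # insert missing axes and order as (T)CZYX
    for missing in set("CZYX") - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = "TCZYX" if "T" in axes else "CZYX"
    data = np.transpose(data, [axes.index(a) for a in order])
    data = _normalise(data)
    n_c = data.shape[-4]
    roles = {r: i for r, i in config.channel_roles.items() if i < n_c}
    if "wall" not in roles or "erbody" not in roles:
        if n_c == 1:
            roles = {"wall": 0, "erbody": 0}
        else:
            raise ValueError(
                f"config channel_roles {config.channel_roles} do not fit a "
                f"{n_c}-channel image"
            )
    return ImageVolume(
        data,
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        channel_roles=roles,
    )


def write_stack(volume: ImageVolume | np.ndarray, path: str | Path, *, dtype=np.uint16) -> None:
    """Write an image (volume or label map) as a multi-page TIFF."""
    arr = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.round(arr * np.iinfo(dtype).max).astype(dtype)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with a stable column order and lossless floats.

    Floats are written with ``repr`` precision so that
    ``read_table(write_table(x))`` reproduces every numeric value to better
    than 1e-12 relative tolerance.
    """
    records.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table`."""
    return pd.read_csv(Path(path))
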