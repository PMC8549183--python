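"""Maximum-contrast projection of confocal z-stacks.

Mean- and max-intensity projections over-represent out-of-focus planes; a
contrast-driven projection instead copies, for every pixel, the intensity
from the z slice where the *local contrast* (sample variance in a small
window) is highest — i.e. the slice where that pixel is in focus.  The map
of winning slice indices is kept so later stages can reason about depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import ImageVolume

__all__ = ["Projection", "local_contrast", "max_contrast_project", "project_volume"]


@dataclass
class Projection:
    """A projected channel plus provenance maps.

    ``image[y, x]`` equals the input intensity at
    ``(index_map[y, x], y, x)`` whenever index-map smoothing is disabled.
    """

    image: np.ndarray         # (Y,X) float in [0,1]
    index_map: np.ndarray     # (Y,X) int, winning z slice per pixel
    contrast_map: np.ndarray  # (Y,X) float, winning contrast value
    channels: dict | None = None   # role -> projected (Y,X) image for other channels
    pixel_size_um: float = 1.0

    def channel(self, role: str) -> np.ndarray:
        if self.channels and role in self.channels:
            return self.channels[role]
        raise KeyError(f"no projected channel for role {role!r}")


def local_contrast(slice_2d: np.ndarray, window_radius: int = 3) -> np.ndarray:
    """Per-pixel sample variance in a (2r+1)x(2r+1) window, reflect-padded.

    Sample (ddof=1) variance is used so the statistic is an unbiased
    estimate of local intensity variance.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    img = np.asarray(slice_2d, dtype=np.float64)
    size = 2 * window_radius + 1
    if size > min(img.shape):
        raise ValueError(f"window {size} exceeds image {img.shape}")
    n = size * size
    mean = ndimage.uniform_filter(img, size, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size, mode="reflect")
    var = (mean_sq - mean * mean) * (n / (n - 1))
    return np.clip(var, 0.0, None)


def max_contrast_project(
    stack: ImageVolume | np.ndarray,
    channel: int | str = 0,
    window_radius: int = 3,
    smooth_radius: int = 2,
) -> Projection:
    """Project one channel of a z-stack by per-pixel maximum local contrast.

    Parameters
    ----------
    stack
        ``ImageVolume`` or plain ``(Z, Y, X)`` array.
    channel
        Channel index or role name (when *stack* is an ``ImageVolume``).
    window_radius
        Radius of the local-variance window.
    smooth_radius
        If > 0, the argmax index map is median-filtered with a
        ``(2r+1)``-sized footprint before sampling intensities, removing
        salt-and-pepper slice switching in flat regions.

    Ties in the contrast argmax are broken toward the smaller z index.
    """
    if isinstance(stack, ImageVolume):
        planes = stack.channel(channel) if isinstance(channel, str) else (
            stack.data[0, channel] if stack.has_time else stack.data[channel]
        )
        px = stack.pixel_size_um
    else:
        planes = np.asarray(stack, dtype=np.float64)
        px = 1.0
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("need a (Z, Y, X) stack with >= 1 slice")

    contrast = np.stack([local_contrast(p, window_radius) for p in planes])
    index_map = np.argmax(contrast, axis=0)  # first max -> smaller z wins ties
    if smooth_radius > 0 and planes.shape[0] > 1:
        index_map = ndimage.median_filter(
            index_map, size=2 * smooth_radius + 1, mode="reflect"
        )
    yy, xx = np.indices(index_map.shape)
    image = planes[index_map, yy, xx]
    return Projection(
        image=image,
        index_map=index_map.astype(np.int64),
        contrast_map=contrast[index_map, yy, xx],
        pixel_size_um=px,
    )


def mean_project(planes: np.ndarray) -> np.ndarray:
    """Plain mean-intensity projection (comparison mode, untuned)."""
    return np.asarray(planes, dtype=np.float64).mean(axis=0)


def max_project(planes: np.ndarray) -> np.ndarray:
    """Plain max-intensity projection (comparison mode, untuned)."""
    return np.asarray(planes, dtype=np.float64).max(axis=0)


def project_volume(
    stack: ImageVolume,
    window_radius: int = 3,
    smooth_radius: int = 2,
    frame: int | None = None,
) -> Projection:
    """Project every channel of a volume; contrast maps from the reporter.

    The reporter (``erbody``) channel drives the headline projection; each
    other role is projected the same way and attached under ``channels`` so
    segmentation can use the projected wall image.
    """
    projections: dict[str, np.ndarray] = {}
    main_proj: Projection | None = None
    for role in stack.channel_roles:
        planes = stack.channel(role, frame)
        proj = max_contrast_project(planes, 0, window_radius, smooth_radius)
        projections[role] = proj.image
        if role == "erbody":
            main_proj = proj
    assert main_proj is not None
    main_proj.channels = projections
    main_proj.pixel_size_um = stack.pixel_size_um
    return main_proj
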