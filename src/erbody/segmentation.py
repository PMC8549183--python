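"""Cell and ER-body segmentation.

Cells are recovered from the projected wall channel: adaptive thresholding
detects the bright wall lines, the complement of the (closed, hole-filled)
wall mask yields one seed region per cell interior, and a seeded Voronoi
propagation assigns every pixel to its nearest seed under a metric that
mixes geometric path length with the wall-intensity gradient, so boundaries
follow the walls.  Cells below a minimum area (default 5000 px) are
discarded.

ER bodies are then extracted per cell from the reporter channel: pixels
above the cell's 97% intensity quantile that also clear a global Otsu
threshold, split into connected components and filtered by an area window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import graph as skgraph
from skimage import morphology

from .imgio import PipelineConfig
from .projection import Projection

__all__ = [
    "LabelMap",
    "CellRecord",
    "adaptive_threshold",
    "quantile_threshold",
    "otsu_threshold",
    "voronoi_propagate",
    "segment_cells",
    "segment_erbodies",
]

STRUCT4 = ndimage.generate_binary_structure(2, 1)
STRUCT8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class LabelMap:
    """Integer label image: 0 = background, labels 1..n_objects."""

    labels: np.ndarray
    provenance: str  # "cell" or "erbody"
    cell_of: dict | None = None      # erbody label -> enclosing cell label
    border_flags: dict | None = None  # cell label -> touches image border

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.min() < 0:
            raise ValueError("labels must be a 2D nonnegative integer image")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def areas(self) -> np.ndarray:
        """Pixel count per label 1..n (index 0 unused)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)


@dataclass
class CellRecord:
    cell_id: int
    image_id: str
    area_px: int
    bbox: tuple  # (y0, x0, y1, x1)
    touches_border: bool
    has_erbody_candidates: bool = False


def _local_mean(image: np.ndarray, window_px: int) -> np.ndarray:
    return ndimage.uniform_filter(
        np.asarray(image, dtype=np.float64), window_px, mode="reflect"
    )


def adaptive_threshold(image: np.ndarray, window_px: int = 31, offset: float = 0.02) -> np.ndarray:
    """Mask of pixels brighter than their reflect-padded local mean + offset."""
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    image = np.asarray(image, dtype=np.float64)
    if window_px > min(image.shape):
        raise ValueError(f"window {window_px} exceeds image {image.shape}")
    return image > _local_mean(image, window_px) + offset


def quantile_threshold(image: np.ndarray, q: float, roi: np.ndarray) -> np.ndarray:
    """Pixels inside *roi* strictly above the q-quantile of roi intensities.

    Quantiles use linear interpolation of order statistics (type 7), the
    numpy default; on a constant region no pixel exceeds the quantile and
    the mask is empty.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty roi")
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    image = np.asarray(image, dtype=np.float64)
    cut = np.quantile(image[roi], q)
    out = np.zeros_like(roi)
    out[roi] = image[roi] > cut
    return out


def otsu_threshold(image: np.ndarray, n_bins: int = 256, roi: np.ndarray | None = None) -> float:
    """Histogram bin edge maximising the between-class variance.

    Classes are split as ``value <= t`` vs ``value > t`` where ``t`` runs
    over interior bin edges of an equal-width histogram of the observed
    intensity range.
    """
    image = np.asarray(image, dtype=np.float64)
    vals = image[np.asarray(roi, bool)] if roi is not None else image.ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("constant image has no Otsu threshold")
    hist, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(p)[:-1]                      # class weight below each interior edge
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_total - m[:-1]) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return float(edges[1:-1][np.argmax(between)])


def voronoi_propagate(
    seeds: np.ndarray,
    wall_image: np.ndarray | None = None,
    lam: float = 10.0,
) -> np.ndarray:
    """Assign every pixel to a seed region by smallest travel cost.

    With ``lam == 0`` the metric is plain Euclidean distance to the nearest
    seed pixel (exact geometric Voronoi partition of the seed regions).
    With ``lam > 0`` the cost of a path accumulates
    ``step_length + lam * |grad wall|`` per pixel, so crossing a bright
    wall line is expensive and boundaries settle onto the walls
    (Dijkstra-style minimum-cost flood via ``skimage.graph.MCP_Geometric``).
    """
    seeds = np.asarray(seeds)
    if seeds.max() == 0:
        return np.zeros_like(seeds)
    if lam == 0 or wall_image is None:
        # exact nearest-seed-pixel partition
        dist, (iy, ix) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
        return seeds[iy, ix]
    gy, gx = np.gradient(np.asarray(wall_image, dtype=np.float64))
    cost = 1.0 + lam * np.hypot(gy, gx)
    mcp = skgraph.MCP_Geometric(cost)
    starts = np.argwhere(seeds > 0)
    costs, traceback = mcp.find_costs(starts)
    # walk traceback offsets (in cost order) to the originating seed label
    labels = np.zeros_like(seeds)
    labels[seeds > 0] = seeds[seeds > 0]
    order = np.argsort(costs, axis=None, kind="stable")
    flat_labels = labels.ravel()
    offsets = np.asarray(mcp.offsets, dtype=np.int64)
    h, w = seeds.shape
    for flat in order:
        if flat_labels[flat]:
            continue
        y, x = divmod(int(flat), w)
        tb = traceback[y, x]
        if tb < 0:
            continue
        oy, ox = int(offsets[tb, 0]), int(offsets[tb, 1])
        src = (y - oy) * w + (x - ox)
        flat_labels[flat] = flat_labels[src]
    return labels


def segment_cells(
    projection: Projection,
    config: PipelineConfig | None = None,
    image_id: str = "image",
) -> tuple[LabelMap, list[CellRecord]]:
    """Segment cells from the projected wall channel.

    Pipeline: adaptive threshold on the wall image -> morphological closing
    and hole filling of the wall mask -> connected components of its
    complement (area >= ``min_seed_area_px``) as seeds -> seeded Voronoi
    propagation -> drop cells smaller than ``min_cell_area_px`` and relabel
    ``1..N``.  Cells touching the image border are kept but flagged.
    """
    config = config or PipelineConfig()
    wall = projection.channel("wall") if projection.channels else projection.image
    if config.wall_smooth_sigma > 0:
        # suppress shot noise so the adaptive threshold traces walls, not speckle
        wall = ndimage.gaussian_filter(wall, config.wall_smooth_sigma)
    wall_mask = adaptive_threshold(wall, config.threshold_window_px, config.threshold_offset)
    if config.closing_radius > 0:
        selem = morphology.disk(config.closing_radius)
        wall_mask = ndimage.binary_closing(wall_mask, structure=selem)

    seeds_bin = ~wall_mask
    # the outermost pixels cannot seed a cell: a bright frame at the field
    # edge otherwise leaves a ring-shaped sliver in the wall-mask complement
    m = 4
    seeds_bin[:m, :] = seeds_bin[-m:, :] = False
    seeds_bin[:, :m] = seeds_bin[:, -m:] = False
    seed_labels, _ = ndimage.label(seeds_bin, structure=STRUCT4)
    sizes = np.bincount(seed_labels.ravel())
    small = np.flatnonzero(sizes < config.min_seed_area_px)
    seed_labels[np.isin(seed_labels, small)] = 0

    if seed_labels.max() == 0:
        return LabelMap(np.zeros_like(seed_labels), "cell"), []

    labels = voronoi_propagate(seed_labels, wall, config.voronoi_lambda)

    # area filter + relabel 1..N (order preserved)
    areas = np.bincount(labels.ravel())
    keep = [l for l in range(1, len(areas)) if areas[l] >= config.min_cell_area_px]
    remap = np.zeros(len(areas), dtype=labels.dtype)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    labels = remap[labels]

    records: list[CellRecord] = []
    border_flags: dict[int, bool] = {}
    slices = ndimage.find_objects(labels)
    h, w = labels.shape
    for cid, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        ys, xs = sl
        touches = ys.start == 0 or xs.start == 0 or ys.stop == h or xs.stop == w
        border_flags[cid] = touches
        records.append(CellRecord(
            cell_id=cid,
            image_id=image_id,
            area_px=int((labels[sl] == cid).sum()),
            bbox=(ys.start, xs.start, ys.stop, xs.stop),
            touches_border=touches,
        ))
    return LabelMap(labels, "cell", border_flags=border_flags), records


def segment_erbodies(
    projection: Projection,
    cells: LabelMap,
    config: PipelineConfig | None = None,
) -> LabelMap:
    """Segment ER-body objects within each segmented cell.

    Per cell the reporter image is thresholded at the cell's
    ``erbody_quantile`` intensity quantile (default 0.97) AND a global Otsu
    threshold; 8-connected components within the area window
    ``[min_erbody_px, max_erbody_px]`` become objects.  Each object is
    assigned to the cell containing its centroid (ties toward the smaller
    cell id by scan order).
    """
    config = config or PipelineConfig()
    if cells.n_objects == 0:
        return LabelMap(np.zeros_like(cells.labels), "erbody", cell_of={})
    green = projection.channel("erbody") if projection.channels else projection.image
    try:
        otsu = otsu_threshold(green, 256)
    except ValueError:
        otsu = np.inf  # constant image: nothing passes
    candidate = np.zeros(green.shape, dtype=bool)
    for cid in range(1, cells.n_objects + 1):
        roi = cells.labels == cid
        if not roi.any():
            continue
        qmask = quantile_threshold(green, config.erbody_quantile, roi)
        candidate |= qmask & (green > otsu)

    comp, n = ndimage.label(candidate, structure=STRUCT8)
    out = np.zeros_like(comp)
    cell_of: dict[int, int] = {}
    next_id = 0
    objects = ndimage.find_objects(comp)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        m = comp[sl] == lab
        area = int(m.sum())
        if not config.min_erbody_px <= area <= config.max_erbody_px:
            continue
        # ER bodies are a dense, bright signal; dim ER-network speckle is not
        if float(green[sl][m].mean()) < config.min_erbody_intensity:
            continue
        ys, xs = np.nonzero(m)
        cy = ys.mean() + sl[0].start
        cx = xs.mean() + sl[1].start
        cid = int(cells.labels[int(round(cy)), int(round(cx))])
        if cid == 0:
            # centroid fell on a boundary pixel: take the smallest adjacent cell id
            inside = cells.labels[sl][m]
            inside = inside[inside > 0]
            if inside.size == 0:
                continue
            cid = int(inside.min())
        next_id += 1
        out[sl][m] = next_id
        cell_of[next_id] = cid
    return LabelMap(out, "erbody", cell_of=cell_of)
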