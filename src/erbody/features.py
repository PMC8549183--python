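"""Per-object feature extraction: the 40-feature phenotype profile.

Every segmented ER-body object is described by

* 6 spatial features (``s.*``): area, perimeter and boundary-radius
  statistics, all in pixel units;
* 8 intensity features (``b.*``): mean, sd, median absolute deviation and
  five quantiles of the reporter intensity under the object mask;
* 26 Haralick texture features (``h.*.s1`` / ``h.*.s2``): the 13 classic
  co-occurrence statistics computed from a masked, direction-pooled,
  symmetric grey-level co-occurrence matrix (GLCM) at two pixel offsets
  (scales ``s1`` and ``s2``).

plus the intensity-weighted centroid ``m.cx`` / ``m.cy`` (pixel
coordinates, x = column) used by the dynamics stage, and optional Zernike
moment magnitudes (rotation-invariant shape descriptors, off by default —
the statistical block is the 40 features above).

Conventions that matter for reproducibility: grey levels are equal-width
bins of [0, 1]; the four offsets 0/45/90/135 degrees are pooled into one
symmetric GLCM per scale before statistics are taken; entropies use log
base 2 with 0*log(0) = 0; quantiles interpolate order statistics linearly
(type 7).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import PipelineConfig
from .projection import Projection
from .segmentation import STRUCT4, LabelMap

__all__ = [
    "SPATIAL_FEATURES",
    "INTENSITY_FEATURES",
    "HARALICK_NAMES",
    "FEATURE_COLUMNS",
    "quantize",
    "glcm",
    "haralick13",
    "shape_features",
    "intensity_features",
    "zernike_moments",
    "weighted_centroid",
    "assemble_feature_matrix",
]

SPATIAL_FEATURES = [
    "s.area", "s.perimeter", "s.radius.mean", "s.radius.sd",
    "s.radius.min", "s.radius.max",
]
INTENSITY_FEATURES = [
    "b.mean", "b.sd", "b.mad", "b.q001", "b.q005", "b.q05", "b.q095", "b.q099",
]
HARALICK_NAMES = [
    "asm", "con", "cor", "var", "idm", "sav", "sva",
    "sen", "ent", "dva", "den", "f12", "f13",
]
#: the 40-feature statistical block, in stable column order
FEATURE_COLUMNS = (
    SPATIAL_FEATURES
    + INTENSITY_FEATURES
    + [f"h.{n}.s{s}" for s in (1, 2) for n in HARALICK_NAMES]
)
METADATA_COLUMNS = [
    "feature_id", "level", "image_id", "cell_id", "object_id",
    "genotype", "setting", "objective", "days_after_germination", "staining",
    "m.cx", "m.cy",
]


def quantize(image: np.ndarray, mask: np.ndarray | None, n_bins: int) -> np.ndarray:
    """Equal-width binning of [0, 1] into integer levels ``0..n_bins-1``.

    Pixels outside *mask* are flagged ``-1`` (invalid).  Quantisation is
    monotone and maps 1.0 into the top bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    image = np.asarray(image, dtype=np.float64)
    levels = np.minimum((image * n_bins).astype(np.int64), n_bins - 1)
    levels = np.maximum(levels, 0)
    if mask is not None:
        levels = np.where(np.asarray(mask, bool), levels, -1)
    return levels


# (dy, dx) offsets for 0, 45, 90, 135 degrees at unit scale
_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm(levels: np.ndarray, mask: np.ndarray | None = None, scale: int = 1,
         n_bins: int | None = None) -> np.ndarray:
    """Masked, direction-pooled, symmetric, normalised co-occurrence matrix.

    Pair counts are accumulated over the four offsets at ``scale`` pixels
    (0/45/90/135 degrees), keeping only pairs with both pixels valid
    (inside the mask), symmetrised by counting (a, b) and (b, a), and
    normalised to sum to 1.
    """
    levels = np.asarray(levels)
    if mask is not None:
        levels = np.where(np.asarray(mask, bool), levels, -1)
    g = int(n_bins) if n_bins is not None else int(levels.max()) + 1
    if g < 2:
        g = 2
    counts = np.zeros((g, g), dtype=np.float64)
    h, w = levels.shape
    for dy, dx in _DIRECTIONS:
        oy, ox = dy * scale, dx * scale
        ys = slice(max(0, -oy), min(h, h - oy))
        xs = slice(max(0, -ox), min(w, w - ox))
        a = levels[ys, xs]
        b = levels[ys.start + oy: ys.stop + oy, xs.start + ox: xs.stop + ox]
        valid = (a >= 0) & (b >= 0)
        if valid.any():
            np.add.at(counts, (a[valid], b[valid]), 1.0)
            np.add.at(counts, (b[valid], a[valid]), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no valid co-occurring pixel pairs at scale {scale}")
    return counts / total


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick13(p: np.ndarray) -> dict[str, float]:
    """The 13 classic texture statistics of a normalised symmetric GLCM.

    Returns a dict keyed by the short names in :data:`HARALICK_NAMES`:
    angular second moment, contrast, correlation, variance (sum of
    squares), inverse difference moment, sum average, sum variance, sum
    entropy, entropy, difference variance, difference entropy, and the two
    information measures of correlation.  Degenerate cases (zero marginal
    variance) return 0 for the affected correlation-type features.
    """
    p = np.asarray(p, dtype=np.float64)
    g = p.shape[0]
    i = np.arange(g, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)          # symmetric: px == py
    mu = float((i * px).sum())
    var_x = float(((i - mu) ** 2 * px).sum())
    sd_x = math.sqrt(var_x)

    # sum / difference distributions
    psum = np.zeros(2 * g - 1)   # index k = i + j
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    pdiff = np.zeros(g)          # index k = |i - j|
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    ks = np.arange(2 * g - 1, dtype=np.float64)
    kd = np.arange(g, dtype=np.float64)

    asm = float((p ** 2).sum())
    con = float((kd ** 2 * pdiff).sum())
    cor = float(((ii * jj * p).sum() - mu * mu) / var_x) if var_x > 0 else 0.0
    var = float((((ii - mu) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sav = float((ks * psum).sum())
    sva = float(((ks - sav) ** 2 * psum).sum())
    sen = float(-_xlog2(psum).sum())
    ent = float(-_xlog2(p).sum())
    mud = float((kd * pdiff).sum())
    dva = float(((kd - mud) ** 2 * pdiff).sum())
    den = float(-_xlog2(pdiff).sum())

    # information measures of correlation
    hx = float(-_xlog2(px).sum())
    outer = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer * log_outer).sum())
    f12 = (ent - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - ent))
    f13 = math.sqrt(arg) if arg > 0 else 0.0

    return dict(asm=asm, con=con, cor=cor, var=var, idm=idm, sav=sav, sva=sva,
                sen=sen, ent=ent, dva=dva, den=den, f12=f12, f13=f13)


def shape_features(object_mask: np.ndarray) -> dict[str, float]:
    """Area, 4-connected perimeter and boundary-radius statistics.

    The perimeter counts exposed pixel edges (4-connected border
    transitions, image border included).  Radii are distances from
    boundary pixels to the binary centroid of the object.
    """
    m = np.asarray(object_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty object mask")
    area = float(m.sum())
    pad = np.pad(m, 1)
    perim = 0
    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        perim += int((pad & ~np.roll(pad, (dy, dx), axis=(0, 1))).sum())

    ys, xs = np.nonzero(m)
    cy, cx = ys.mean(), xs.mean()
    boundary = m & ~ndimage.binary_erosion(m, STRUCT4, border_value=0)
    by, bx = np.nonzero(boundary)
    r = np.hypot(by - cy, bx - cx)
    return {
        "s.area": area,
        "s.perimeter": float(perim),
        "s.radius.mean": float(r.mean()),
        "s.radius.sd": float(r.std()),
        "s.radius.min": float(r.min()),
        "s.radius.max": float(r.max()),
    }


def intensity_features(image: np.ndarray, object_mask: np.ndarray) -> dict[str, float]:
    """Mean, sd, MAD and the 1/5/50/95/99% quantiles under the mask."""
    m = np.asarray(object_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty object mask")
    v = np.asarray(image, dtype=np.float64)[m]
    med = float(np.median(v))
    q = np.quantile(v, [0.01, 0.05, 0.5, 0.95, 0.99])
    return {
        "b.mean": float(v.mean()),
        "b.sd": float(v.std()),
        "b.mad": float(np.median(np.abs(v - med))),
        "b.q001": float(q[0]),
        "b.q005": float(q[1]),
        "b.q05": float(q[2]),
        "b.q095": float(q[3]),
        "b.q099": float(q[4]),
    }


def weighted_centroid(image: np.ndarray, object_mask: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid (cx, cy) in pixel coordinates."""
    m = np.asarray(object_mask, dtype=bool)
    w = np.asarray(image, dtype=np.float64) * m
    tot = w.sum()
    if tot <= 0:  # fall back to binary centroid for zero-intensity objects
        ys, xs = np.nonzero(m)
        return float(xs.mean()), float(ys.mean())
    ys, xs = np.indices(m.shape)
    return float((w * xs).sum() / tot), float((w * ys).sum() / tot)


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_moments(image: np.ndarray, object_mask: np.ndarray,
                    max_order: int = 12) -> dict[str, float]:
    """Zernike moment magnitudes |A_nm| over the object's bounding disk.

    The disk is centred on the binary centroid with radius equal to the
    farthest mask pixel; intensities weight the projection.  Magnitudes are
    rotation-invariant by construction.
    """
    if max_order > 12:
        raise ValueError("max_order must be <= 12")
    m_arr = np.asarray(object_mask, dtype=bool)
    if not m_arr.any():
        raise ValueError("empty object mask")
    img = np.asarray(image, dtype=np.float64) * m_arr
    ys, xs = np.nonzero(m_arr)
    cy, cx = ys.mean(), xs.mean()
    radius = max(float(np.hypot(ys - cy, xs - cx).max()), 1.0)

    yy, xx = np.nonzero(m_arr)
    rho = np.hypot(yy - cy, xx - cx) / radius
    theta = np.arctan2(yy - cy, xx - cx)
    inside = rho <= 1.0
    rho, theta = rho[inside], theta[inside]
    w = img[yy[inside], xx[inside]]

    out: dict[str, float] = {}
    for n in range(max_order + 1):
        for m in range(0, n + 1):
            if (n - m) % 2:
                continue
            r = _radial_poly(n, m, rho)
            a = (n + 1) / np.pi * np.sum(w * r * np.exp(-1j * m * theta)) / radius ** 2
            out[f"z.{n}{m}"] = float(np.abs(a))
    return out


def object_features(
    green: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig,
) -> dict[str, float]:
    """All 40 features plus centroid for a single object mask."""
    feats: dict[str, float] = {}
    feats.update(shape_features(mask))
    feats.update(intensity_features(green, mask))
    levels = quantize(green, mask, config.glcm_bins)
    for si, scale in enumerate(config.glcm_scales, start=1):
        try:
            g = glcm(levels, None, scale, n_bins=config.glcm_bins)
            stats = haralick13(g)
        except ValueError:
            # object too thin for this offset: no texture signal at this scale
            stats = {k: 0.0 for k in HARALICK_NAMES}
        feats.update({f"h.{k}.s{si}": v for k, v in stats.items()})
    cx, cy = weighted_centroid(green, mask)
    feats["m.cx"], feats["m.cy"] = cx, cy
    if config.include_zernike:
        feats.update(zernike_moments(green, mask, config.zernike_order))
    return feats


def assemble_feature_matrix(
    objects: LabelMap,
    cells: LabelMap,
    projection: Projection,
    metadata: dict | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One row per ER-body object, plus per-cell and per-image aggregates.

    Rows are tagged by the ``level`` column: ``object`` rows carry one
    object's features; ``cell`` rows the mean over the cell's objects; the
    ``image`` row the mean over its cell rows.  A retained cell with *no*
    detected objects still gets a cell row, profiled over its reporter
    candidate mask (the above-quantile signal inside the cell) — this is
    what makes cells devoid of ER bodies separable from body-bearing cells
    in the downstream ordination.  Objects whose pixels touch the image
    border are excluded (truncated objects bias shape features).
    ``n_objects`` counts member objects per row.
    """
    from .segmentation import quantile_threshold

    config = config or PipelineConfig()
    metadata = metadata or {}
    image_id = str(metadata.get("image_id", "image"))
    meta = {
        "genotype": metadata.get("genotype", "NA"),
        "setting": metadata.get("setting", "NA"),
        "objective": metadata.get("objective", "NA"),
        "days_after_germination": metadata.get("days_after_germination", "NA"),
        "staining": metadata.get("staining", "NA"),
    }
    green = projection.channel("erbody") if projection.channels else projection.image
    cell_of = objects.cell_of or {}

    rows = []
    h, w = objects.labels.shape
    slices = ndimage.find_objects(objects.labels)
    for oid, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        cid = cell_of.get(oid, 0)
        if cid == 0:
            raise ValueError(f"object {oid} references no cell")
        if (sl[0].start == 0 or sl[1].start == 0
                or sl[0].stop == h or sl[1].stop == w):
            continue  # truncated at the image border
        m = objects.labels[sl] == oid
        feats = object_features(green[sl], m, config)
        feats["m.cx"] += sl[1].start
        feats["m.cy"] += sl[0].start
        row = {
            "feature_id": f"{image_id}:c{cid}:o{oid}",
            "level": "object", "image_id": image_id,
            "cell_id": cid, "object_id": oid, "n_objects": 1, **meta,
        }
        row.update(feats)
        rows.append(row)
    df = pd.DataFrame(rows)

    agg_cols = FEATURE_COLUMNS + ["m.cx", "m.cy"]
    cell_rows = []
    for cid in range(1, cells.n_objects + 1):
        row = {
            "feature_id": f"{image_id}:c{cid}", "level": "cell",
            "image_id": image_id, "cell_id": cid, "object_id": 0, **meta,
        }
        if not df.empty and (df["cell_id"] == cid).any():
            sub = df[df["cell_id"] == cid]
            row["n_objects"] = int(len(sub))
            row.update(sub[agg_cols].mean().to_dict())
        else:
            roi = cells.labels == cid
            if not roi.any():
                continue
            cand = quantile_threshold(green, config.erbody_quantile, roi)
            if not cand.any():
                continue
            row["n_objects"] = 0
            feats = object_features(green, cand, config)
            row.update(feats)
        cell_rows.append(row)
    cell_df = pd.DataFrame(cell_rows)

    if cell_df.empty:
        return pd.DataFrame(columns=METADATA_COLUMNS + ["n_objects"] + FEATURE_COLUMNS)
    img_row = {
        "feature_id": image_id, "level": "image",
        "image_id": image_id, "cell_id": 0, "object_id": 0,
        "n_objects": int(cell_df["n_objects"].sum()), **meta,
    }
    img_row.update(cell_df[agg_cols].mean().to_dict())

    out = pd.concat([df, cell_df, pd.DataFrame([img_row])], ignore_index=True)
    ordered = [c for c in METADATA_COLUMNS + ["n_objects"] + FEATURE_COLUMNS + ["m.cx", "m.cy"]
               if c in out.columns]
    ordered = list(dict.fromkeys(ordered))
    return out[ordered]
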