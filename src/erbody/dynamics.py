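"""ER-body movement from time-lapse stacks.

The time-0 positions are burned into the blue channel of every frame, so a
single frame shows both the current (green) and initial (blue) object
positions.  Objects are linked across frames by greedy mutual-nearest
centroid matching anchored at frame 0 (no new tracks start mid-series),
displacement is summarised per object per frame, and genotype differences
are tested with a Gaussian GLM (displacement ~ genotype + time) followed by
all-pairs Tukey HSD contrasts with Benjamini-Hochberg adjustment.

Two displacement metrics are computed side by side:

* ``euclidean_um`` — |p_t - p_0| in micrometres; the headline metric.
* ``cosine`` — 1 - cos(p_0, p_t) with positions taken relative to the
  enclosing cell's frame-0 centroid.  A raw image-origin cosine would
  depend on where the cell sits in the field; referencing the cell centroid
  makes it translation-invariant.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .imgio import ImageVolume, PipelineConfig
from .projection import project_volume
from .segmentation import LabelMap, segment_cells, segment_erbodies

__all__ = [
    "encode_t0",
    "track_objects",
    "displacement",
    "loess",
    "trend_and_test",
    "export_movie_frames",
    "extract_timelapse_tracks",
]

TRACK_COLUMNS = ["object_id", "cell_id", "frame", "time_s", "cx_px", "cy_px", "matched"]


def encode_t0(stack: ImageVolume) -> ImageVolume:
    """Copy the frame-0 reporter channel into every frame's t0 channel.

    If the volume has no ``t0`` channel yet, one is appended.
    """
    if not stack.has_time:
        raise ValueError("encode_t0 needs a time axis")
    if "erbody" not in stack.channel_roles:
        raise ValueError("missing reporter (erbody) channel")
    data = stack.data.copy()
    green = stack.channel_roles["erbody"]
    roles = dict(stack.channel_roles)
    if "t0" in roles:
        blue = roles["t0"]
    else:
        data = np.concatenate([data, np.zeros_like(data[:, :1])], axis=1)
        blue = data.shape[1] - 1
        roles["t0"] = blue
    data[:, blue] = data[0, green][None]
    return ImageVolume(data, pixel_size_um=stack.pixel_size_um,
                       z_step_um=stack.z_step_um, channel_roles=roles)


def track_objects(
    per_frame: list[pd.DataFrame],
    max_link_um: float = 3.0,
    pixel_size_um: float = 1.0,
    dt_s: float = 1.0,
) -> pd.DataFrame:
    """Link per-frame detections into frame-0-anchored tracks.

    Each element of *per_frame* holds one frame's detections with columns
    ``cx_px``, ``cy_px`` and optionally ``cell_id``.  Linking is greedy
    mutual-nearest within ``max_link_um``: a track and a detection link only
    if each is the other's nearest partner.  Detections that link to no
    frame-0 track are dropped; tracks that miss a frame carry
    ``matched=False`` there (holding their last seen position) but remain
    linkable later.
    """
    if not per_frame:
        raise ValueError("need at least one frame of detections")
    f0 = per_frame[0].reset_index(drop=True)
    n_tracks = len(f0)
    pos = f0[["cx_px", "cy_px"]].to_numpy(dtype=np.float64)
    cells = f0["cell_id"].to_numpy() if "cell_id" in f0 else np.zeros(n_tracks, int)
    max_link_px = max_link_um / pixel_size_um

    rows = [
        dict(object_id=i + 1, cell_id=int(cells[i]), frame=0, time_s=0.0,
             cx_px=pos[i, 0], cy_px=pos[i, 1], matched=True)
        for i in range(n_tracks)
    ]
    for t in range(1, len(per_frame)):
        det = per_frame[t][["cx_px", "cy_px"]].to_numpy(dtype=np.float64)
        matched = np.zeros(n_tracks, dtype=bool)
        new_pos = pos.copy()
        if len(det):
            d = np.linalg.norm(pos[:, None, :] - det[None, :, :], axis=2)
            nearest_det = np.argmin(d, axis=1)
            nearest_trk = np.argmin(d, axis=0)
            for i in range(n_tracks):
                j = nearest_det[i]
                if nearest_trk[j] == i and d[i, j] <= max_link_px:
                    matched[i] = True
                    new_pos[i] = det[j]
        pos = new_pos
        for i in range(n_tracks):
            rows.append(dict(object_id=i + 1, cell_id=int(cells[i]), frame=t,
                             time_s=t * dt_s, cx_px=pos[i, 0], cy_px=pos[i, 1],
                             matched=bool(matched[i])))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def displacement(
    tracks: pd.DataFrame,
    pixel_size_um: float = 1.0,
    cell_centroids: dict | None = None,
    window: int = 3,
) -> pd.DataFrame:
    """Per-object per-frame displacement from the frame-0 position.

    ``euclidean_um = |p_t - p_0| * pixel_size_um``;
    ``cosine = 1 - (p_0 . p_t) / (|p_0||p_t|)`` with positions relative to
    the enclosing cell's frame-0 centroid (supplied via *cell_centroids*,
    label -> (cx, cy); defaults to the mean frame-0 position of the cell's
    objects).  Zero-norm reference vectors make the cosine term undefined:
    those rows carry ``cosine=NaN`` and ``cosine_valid=False``.  Both
    metrics get a centred moving average over *window* frames, truncated at
    the series ends.
    """
    if (tracks["frame"] == 0).sum() == 0:
        raise ValueError("tracks must contain frame-0 rows")
    tracks = tracks.sort_values(["object_id", "frame"])
    if cell_centroids is None:
        f0 = tracks[tracks["frame"] == 0]
        cell_centroids = {
            int(c): (sub["cx_px"].mean(), sub["cy_px"].mean())
            for c, sub in f0.groupby("cell_id")
        }
    out = []
    for oid, tr in tracks.groupby("object_id", sort=True):
        tr = tr.sort_values("frame")
        p = tr[["cx_px", "cy_px"]].to_numpy(dtype=np.float64)
        ccx, ccy = cell_centroids.get(int(tr["cell_id"].iat[0]), (0.0, 0.0))
        rel = p - np.array([ccx, ccy])
        p0 = rel[0]
        eu = np.linalg.norm(p - p[0], axis=1) * pixel_size_um
        norms = np.linalg.norm(rel, axis=1)
        valid = (np.linalg.norm(p0) > 1e-12) & (norms > 1e-12)
        cos = np.full(len(rel), np.nan)
        if np.linalg.norm(p0) > 1e-12:
            with np.errstate(invalid="ignore", divide="ignore"):
                cos_sim = (rel @ p0) / (norms * np.linalg.norm(p0))
            cos = np.where(valid, 1.0 - np.clip(cos_sim, -1.0, 1.0), np.nan)
        sub = tr[["object_id", "cell_id", "frame", "time_s", "matched"]].copy()
        sub["euclidean_um"] = eu
        sub["cosine"] = cos
        sub["cosine_valid"] = valid
        sub["euclidean_um_ma"] = _moving_average(eu, window)
        sub["cosine_ma"] = _moving_average(cos, window)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, truncated at the ends, NaN-tolerant."""
    x = np.asarray(x, dtype=np.float64)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        seg = x[max(0, i - half): i + half + 1]
        out[i] = np.nan if np.all(np.isnan(seg)) else np.nanmean(seg)
    return out


def loess(x: np.ndarray, y: np.ndarray, span: float = 0.75,
          x_eval: np.ndarray | None = None) -> np.ndarray:
    """Tricube-weighted local linear regression (LOESS).

    The bandwidth at each evaluation point is the distance to the
    ``ceil(span * n)``-th nearest neighbour; a span above 1 scales the
    maximum distance instead, so the infinite-span limit is an ordinary
    least-squares line.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if x_eval is None:
        x_eval = x
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        if span <= 1:
            k = max(int(np.ceil(span * n)), 2)
            h = np.sort(d)[min(k - 1, n - 1)]
        else:
            h = span * max(d.max(), 1e-12)
        h = max(h, 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        if sw <= 0:
            out[i] = y[np.argmin(d)]
            continue
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 1e-14 else 0.0
        out[i] = ym + slope * (x0 - xm)
    return out


def trend_and_test(
    series: pd.DataFrame,
    genotype_col: str = "genotype",
    value_col: str = "euclidean_um",
    time_col: str = "time_s",
    alpha: float = 0.01,
    span: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Displacement trends per genotype plus all-pairs contrasts.

    Returns ``(trends, contrasts)``:

    * *trends*: LOESS curve of the mean displacement over time for each
      genotype (one fitted value per genotype x time point).
    * *contrasts*: for the Gaussian GLM ``value ~ genotype + time``, every
      genotype pair's adjusted mean difference, Tukey HSD p (studentized
      range), BH-adjusted q, and a flag at ``q <= alpha``.

    Frames within one track are strongly dependent (they share the track's
    frame-0 reference), so the HSD standard error is computed over
    *per-track* time-adjusted mean displacements — the track, not the
    frame, is the independent replicate.  Genotypes represented by a
    single track are dropped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    df = series.dropna(subset=[value_col]).copy()
    df[genotype_col] = df[genotype_col].astype(str)
    # drop genotypes represented by a single track
    if "object_id" in df.columns:
        track_counts = df.groupby(genotype_col)["object_id"].nunique()
        for g, n_tracks in track_counts.items():
            if n_tracks <= 1:
                warnings.warn(f"genotype {g!r} has a single track; dropped")
                df = df[df[genotype_col] != g]
    genotypes = sorted(df[genotype_col].unique())
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes")
    if df[time_col].nunique() < 3:
        raise ValueError("need >= 3 time points")

    trend_rows = []
    for g, sub in df.groupby(genotype_col):
        means = sub.groupby(time_col)[value_col].mean()
        t = means.index.to_numpy(dtype=np.float64)
        fit = loess(t, means.to_numpy(), span=span)
        for ti, fi, mi in zip(t, fit, means.to_numpy()):
            trend_rows.append({genotype_col: g, time_col: ti,
                               "mean": mi, "loess": fi})
    trends = pd.DataFrame(trend_rows)

    # Gaussian GLM: value ~ genotype + time (identity link)
    gdum = pd.get_dummies(df[genotype_col])[genotypes].to_numpy(dtype=np.float64)
    x = np.column_stack([gdum, df[time_col].to_numpy(dtype=np.float64)])
    y = df[value_col].to_numpy(dtype=np.float64)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)

    # per-track time-adjusted means: the independent unit for the contrasts
    beta_time = beta[len(genotypes)]
    adj = df.assign(_adj=y - beta_time * df[time_col].to_numpy(dtype=np.float64))
    unit = "object_id" if "object_id" in adj.columns else time_col
    track_means = adj.groupby([genotype_col, unit])["_adj"].mean().reset_index()
    k = len(genotypes)
    n_tracks = track_means.groupby(genotype_col).size()
    grand = {g: sub["_adj"].mean()
             for g, sub in track_means.groupby(genotype_col)}
    ss_within = sum(((sub["_adj"] - grand[g]) ** 2).sum()
                    for g, sub in track_means.groupby(genotype_col))
    dof = int(n_tracks.sum()) - k
    mse = ss_within / dof if dof > 0 else np.inf

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = genotypes[i], genotypes[j]
            diff = grand[gi] - grand[gj]
            se = np.sqrt(mse * (1.0 / n_tracks[gi] + 1.0 / n_tracks[gj]) / 2.0)
            q_stat = abs(diff) / se if se > 0 else np.inf
            p = float(sstats.studentized_range.sf(q_stat, k, dof))
            rows.append({"genotype_a": gi, "genotype_b": gj,
                         "difference": float(diff), "q_statistic": float(q_stat),
                         "p_tukey": p})
    contrasts = pd.DataFrame(rows)
    contrasts["q_bh"] = multipletests(contrasts["p_tukey"].to_numpy(),
                                      method="fdr_bh")[1]
    contrasts["significant"] = contrasts["q_bh"] <= alpha
    return trends, contrasts


def extract_timelapse_tracks(
    stack: ImageVolume,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, LabelMap, LabelMap]:
    """Segment every frame of an encoded time-lapse and build tracks.

    Cells are segmented once on frame 0 (the wall channel is static);
    ER bodies are re-detected per frame within those cells and linked.
    Returns (tracks, cells, frame-0 erbody label map).
    """
    config = config or PipelineConfig()
    if not stack.has_time:
        raise ValueError("need a time-lapse volume")
    proj0 = project_volume(stack, config.window_radius, config.smooth_radius, frame=0)
    cells, _ = segment_cells(proj0, config)
    detections = []
    obj0 = None
    for t in range(stack.n_frames):
        proj = proj0 if t == 0 else project_volume(
            stack, config.window_radius, config.smooth_radius, frame=t)
        objs = segment_erbodies(proj, cells, config)
        if t == 0:
            obj0 = objs
        rows = []
        for oid in range(1, objs.n_objects + 1):
            ys, xs = np.nonzero(objs.labels == oid)
            rows.append(dict(cx_px=xs.mean(), cy_px=ys.mean(),
                             cell_id=(objs.cell_of or {}).get(oid, 0)))
        detections.append(pd.DataFrame(rows, columns=["cx_px", "cy_px", "cell_id"]))
    tracks = track_objects(detections, config.max_link_um, stack.pixel_size_um)
    return tracks, cells, obj0


def export_movie_frames(stack: ImageVolume, out_dir: str | Path,
                        tracks: pd.DataFrame | None = None) -> list[Path]:
    """Write one RGB PNG per frame: red = walls, green = current, blue = t0."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not stack.has_time:
        raise ValueError("need a time-lapse volume")
    paths = []
    width = max(len(str(stack.n_frames - 1)), 3)
    for t in range(stack.n_frames):
        rgb = np.zeros((*stack.shape_yx, 3))
        rgb[..., 0] = stack.channel("wall", t).max(axis=0)
        rgb[..., 1] = stack.channel("erbody", t).max(axis=0)
        if "t0" in stack.channel_roles:
            rgb[..., 2] = stack.channel("t0", t).max(axis=0)
        img = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
        path = out_dir / f"frame_{t:0{width}d}.png"
        iio.imwrite(path, img)
        paths.append(path)
    return paths
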