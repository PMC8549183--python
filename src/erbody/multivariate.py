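"""Multivariate phenotype statistics.

The feature matrix produced by :mod:`erbody.features` is analysed with the
toolchain typical of community-ecology style morphometrics:

* z-scoring per stratum, Pearson-correlation dissimilarity (d = 1 - r,
  range [0, 2]);
* classical (metric) multidimensional scaling by double centering and
  eigendecomposition;
* k-means clustering with the number of clusters selected by AIC under a
  spherical-Gaussian profile likelihood;
* constrained ordination implemented as distance-based redundancy analysis
  (dbRDA) on the Pearson dissimilarity, with nuisance factors partialled
  out, plus a PERMANOVA permutation test (optionally strata-restricted);
* flexible discriminant analysis (optimal scoring; the linear case is
  exactly LDA) and mixture discriminant analysis (per-class Gaussian
  mixtures with a shared pooled covariance, fitted by EM);
* per-feature one-way F tests with Benjamini-Hochberg FDR control.

Note on naming: the ordination is often labelled "CCA" in this field, but
chi-square canonical correspondence analysis cannot consume a correlation
dissimilarity; what is computed here (and what such pipelines actually run)
is dbRDA on principal coordinates of the dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinationResult",
    "ClusteringResult",
    "PermanovaResult",
    "zscore",
    "pcc_distance",
    "classical_mds",
    "kmeans_aic",
    "constrained_ordination",
    "permanova",
    "FDAModel",
    "fda_fit",
    "MDAModel",
    "mda_fit",
    "confusion_matrix",
    "groupwise_tests",
    "cluster_report",
]


# ---------------------------------------------------------------- results


@dataclass
class OrdinationResult:
    coordinates: np.ndarray          # (n, k) sample scores
    eigenvalues: np.ndarray          # all eigenvalues, descending
    axis_fractions: np.ndarray       # variance fraction per returned axis
    constrained_fraction: float | None = None
    permutation_p: float | None = None


@dataclass
class ClusteringResult:
    labels: np.ndarray               # 1..k per sample
    centroids: np.ndarray
    wcss: float
    aic_trace: dict                  # k -> AIC
    k_selected: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    permutations: int


# ---------------------------------------------------------------- basics


def zscore(
    matrix: pd.DataFrame,
    columns: list[str] | None = None,
    strata: str | list[str] | None = None,
) -> pd.DataFrame:
    """Per-column (optionally per-stratum) z-scores, sample-sd convention.

    Columns that are constant within a stratum are set to 0 and recorded in
    ``result.attrs['constant_columns']``.
    """
    df = matrix.copy()
    if columns is None:
        columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    flagged: set[str] = set()

    def _norm(sub: pd.DataFrame) -> pd.DataFrame:
        out = sub.copy()
        for c in columns:
            sd = sub[c].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                out[c] = 0.0
                flagged.add(c)
            else:
                out[c] = (sub[c] - sub[c].mean()) / sd
        return out

    if strata is None:
        df = _norm(df)
    else:
        if isinstance(strata, str):
            strata = [strata]
        for _, idx in df.groupby(strata, dropna=False).groups.items():
            if len(idx) == 0:
                raise ValueError("empty stratum")
            df.loc[idx] = _norm(df.loc[idx])
    df.attrs["constant_columns"] = sorted(flagged)
    return df


def pcc_distance(matrix: np.ndarray | pd.DataFrame, axis: str = "samples") -> np.ndarray:
    """Pearson dissimilarity d(i, j) = 1 - r(i, j), in [0, 2].

    ``axis='samples'`` correlates rows, ``axis='features'`` columns.
    Zero-variance profiles get distance 1 to everything (with a warning).
    """
    x = np.asarray(matrix, dtype=np.float64)
    if axis == "features":
        x = x.T
    if x.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    sd = x.std(axis=1)
    degenerate = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x)
    d = 1.0 - r
    if degenerate.any():
        warnings.warn(f"{degenerate.sum()} zero-variance profiles: distance set to 1")
        d[degenerate, :] = 1.0
        d[:, degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d


def _gower_center(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    a = -0.5 * d ** 2
    return a - a.mean(0) - a.mean(1)[:, None] + a.mean()


def classical_mds(d: np.ndarray, n_axes: int = 2) -> OrdinationResult:
    """Classical (Torgerson) scaling of a distance matrix.

    The Gower-centred matrix is eigendecomposed; coordinates come from the
    positive eigenvalues; axis variance fractions are eigenvalue shares of
    the positive spectrum.  Negative eigenvalues (non-Euclidean distances)
    are reported in ``eigenvalues`` but carry no coordinates.
    """
    d = np.asarray(d, dtype=np.float64)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    b = _gower_center(d)
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating n_axes")
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    fractions = evals[:n_axes] / evals[pos].sum()
    return OrdinationResult(coords, evals, fractions)


# ---------------------------------------------------------------- k-means


def kmeans_aic(
    matrix: np.ndarray | pd.DataFrame,
    k_range: tuple[int, int] = (6, 100),
    restarts: int = 5,
    rng_seed: int = 0,
) -> ClusteringResult:
    """Best-of-restarts k-means with AIC-based selection of k.

    The criterion is the AIC of the spherical-Gaussian *classification*
    likelihood (the X-means formulation): up to constants,

    ``AIC(k) = n*d*ln(WCSS/(n*d)) - 2*sum_k n_k*ln(n_k/n) + 2*k*(d+1)``.

    The assignment-entropy term is what penalises splitting a coherent
    cluster; a pure profile likelihood (``n*d*ln(WCSS/(n*d)) + 2*k*d``)
    decreases with k essentially without bound and cannot select a finite
    optimum.  The smallest k minimising AIC is selected.
    """
    x = np.asarray(matrix, dtype=np.float64)
    n, dim = x.shape
    lo, hi = int(k_range[0]), int(k_range[1])
    hi = min(hi, n - 1)
    if lo > hi:
        raise ValueError(f"k_range {k_range} infeasible for n={n}")
    trace: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for i, k in enumerate(range(lo, hi + 1)):
        km = KMeans(n_clusters=k, n_init=restarts,
                    random_state=(rng_seed + 7919 * i) % (2 ** 31))
        km.fit(x)
        wcss = max(float(km.inertia_), 1e-300)
        sizes = np.bincount(km.labels_, minlength=k).astype(np.float64)
        sizes = sizes[sizes > 0]
        class_term = float((sizes * np.log(sizes / n)).sum())
        trace[k] = (n * dim * np.log(wcss / (n * dim))
                    - 2.0 * class_term + 2.0 * k * (dim + 1))
        fits[k] = km
    k_sel = min(trace, key=lambda k: (trace[k], k))
    best = fits[k_sel]
    return ClusteringResult(
        labels=best.labels_.astype(int) + 1,
        centroids=best.cluster_centers_,
        wcss=float(best.inertia_),
        aic_trace=trace,
        k_selected=k_sel,
    )


# ------------------------------------------------------- constrained dbRDA


def _dummies(factor, drop_first: bool = False) -> np.ndarray:
    f = pd.Series(factor).astype(str)
    d = pd.get_dummies(f, drop_first=drop_first).to_numpy(dtype=np.float64)
    return d


def _project_out(y: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    """Residualise columns of y on [1, z]."""
    n = y.shape[0]
    design = np.ones((n, 1)) if z is None else np.column_stack([np.ones(n), z])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def constrained_ordination(
    matrix: np.ndarray | pd.DataFrame,
    fixed,
    conditions: list | None = None,
    n_axes: int = 2,
) -> OrdinationResult:
    """Distance-based RDA of the Pearson dissimilarity on a design factor.

    Principal coordinates of the Pearson dissimilarity are residualised
    (together with the fixed-factor dummies) on the condition dummies; the
    constrained axes are the principal axes of the fitted values of the
    multivariate regression of coordinates on the fixed factor.
    ``constrained_fraction`` is constrained inertia over total (conditioned)
    inertia; per-axis fractions are relative to the constrained inertia.
    """
    fixed = np.asarray(pd.Series(fixed).astype(str))
    if len(np.unique(fixed)) < 2:
        raise ValueError("fixed factor needs >= 2 levels")
    d = pcc_distance(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # take all positive axes
        mds = classical_mds(d, n_axes=int(np.asarray(d).shape[0] - 1))
    y = mds.coordinates

    z = None
    if conditions:
        zs = [_dummies(c, drop_first=True) for c in conditions]
        z = np.column_stack([np.ones((y.shape[0], 0))] + zs) if zs else None
    f = _dummies(fixed, drop_first=True)
    yr = _project_out(y, z)
    fr = _project_out(f, z)
    if np.allclose(fr, 0.0, atol=1e-10):
        raise ValueError("fixed factor is confounded with the conditions")

    beta, *_ = np.linalg.lstsq(fr, yr, rcond=None)
    fitted = fr @ beta
    total_inertia = float((yr ** 2).sum())
    constrained_inertia = float((fitted ** 2).sum())
    frac = constrained_inertia / total_inertia if total_inertia > 0 else 0.0

    # principal axes of the fitted values
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    evals = s ** 2
    k = min(n_axes, int((evals > evals.max() * 1e-12).sum()) if evals.size else 0)
    coords = u[:, :k] * s[:k]
    fractions = evals[:k] / evals.sum() if evals.sum() > 0 else np.zeros(k)
    return OrdinationResult(coords, evals, fractions, constrained_fraction=frac)


def permanova(
    d: np.ndarray,
    fixed,
    conditions=None,
    permutations: int = 1000,
    rng_seed: int = 0,
) -> PermanovaResult:
    """Permutational MANOVA pseudo-F on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + permutations)``; when
    *conditions* is given, permutations are restricted within its strata.
    """
    if permutations < 99:
        raise ValueError("permutations must be >= 99")
    d = np.asarray(d, dtype=np.float64)
    n = d.shape[0]
    labels = pd.Series(fixed).astype(str).to_numpy()
    groups, codes = np.unique(labels, return_inverse=True)
    g = len(groups)
    if g < 2:
        raise ValueError("fixed factor needs >= 2 levels")
    gmat = _gower_center(d)
    # Gower-centred rows sum to 0, so the intercept terms vanish and
    # SS_between = sum_g (1' G 1)_g / n_g over within-group blocks
    ss_total = float(np.trace(gmat))
    sizes = np.bincount(codes).astype(np.float64)

    def pseudo_f(c: np.ndarray) -> float:
        onehot = np.zeros((n, g))
        onehot[np.arange(n), c] = 1.0
        block = np.einsum("ig,ij,jg->g", onehot, gmat, onehot)
        ss_between = float((block / sizes).sum())
        ss_within = ss_total - ss_between
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    f_obs = pseudo_f(codes)
    onehot = np.zeros((n, g))
    onehot[np.arange(n), codes] = 1.0
    ss_between = float((np.einsum("ig,ij,jg->g", onehot, gmat, onehot) / sizes).sum())
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(rng_seed)
    if conditions is not None:
        cond_list = conditions if isinstance(conditions, (list, tuple)) else [conditions]
        strata = pd.Series(
            list(zip(*[pd.Series(c).astype(str) for c in cond_list]))
        ).astype(str).to_numpy()
    else:
        strata = None

    count = 0
    idx = np.arange(n)
    for _ in range(permutations):
        if strata is None:
            perm = rng.permutation(idx)
        else:
            perm = idx.copy()
            for s in np.unique(strata):
                sel = np.flatnonzero(strata == s)
                perm[sel] = sel[rng.permutation(len(sel))]
        if pseudo_f(codes[perm]) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return PermanovaResult(f_obs, r2, p, permutations)


# --------------------------------------------------------------- FDA / MDA


@dataclass
class FDAModel:
    """Linear flexible discriminant analysis fitted by optimal scoring."""

    classes: np.ndarray
    mean_: np.ndarray
    directions: np.ndarray           # feature-space -> discriminant space
    centroids: np.ndarray            # class centroids in discriminant space
    cov_inv: np.ndarray              # pooled covariance inverse in that space
    log_priors: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean_) @ self.directions

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = self.transform(x)
        # Mahalanobis nearest centroid with prior correction == LDA rule
        scores = np.empty((z.shape[0], len(self.classes)))
        for k, mu in enumerate(self.centroids):
            diff = z - mu
            scores[:, k] = -0.5 * np.einsum("ij,jk,ik->i", diff, self.cov_inv, diff) \
                + self.log_priors[k]
        return self.classes[np.argmax(scores, axis=1)]


def fda_fit(matrix: np.ndarray | pd.DataFrame, labels, ridge: float = 1e-8) -> FDAModel:
    """Fit linear FDA by optimal scoring.

    The class-indicator matrix is regressed on the (centred) features; the
    eigenvectors of the resulting scoring problem span the canonical
    discriminant subspace, where classification uses Mahalanobis distance
    to class centroids with log-prior correction (identical to classical
    LDA in the linear case).  A tiny ridge stabilises rank-deficient
    scatter.
    """
    x = np.asarray(matrix, dtype=np.float64)
    y = pd.Series(labels).astype(str).to_numpy()
    classes, y_idx = np.unique(y, return_inverse=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need >= 2 classes")
    n, p = x.shape
    mean_ = x.mean(axis=0)
    xc = x - mean_
    ind = np.zeros((n, g))
    ind[np.arange(n), y_idx] = 1.0

    # ridge-regularised multivariate regression of indicators on features
    xtx = xc.T @ xc + ridge * np.eye(p)
    b = np.linalg.solve(xtx, xc.T @ ind)          # (p, g)
    fitted = xc @ b                                # (n, g)
    # optimal scores: eigenvectors of (Y'Y)^-1 Y' fitted
    m = np.diag(1.0 / ind.sum(axis=0)) @ (ind.T @ fitted)
    evals, theta = np.linalg.eig(m)
    order = np.argsort(evals.real)[::-1]
    keep = order[: g - 1]
    directions = (b @ theta[:, keep].real)

    z = xc @ directions
    centroids = np.stack([z[y_idx == k].mean(axis=0) for k in range(g)])
    within = np.zeros((z.shape[1], z.shape[1]))
    for k in range(g):
        r = z[y_idx == k] - centroids[k]
        within += r.T @ r
    within /= (n - g)
    cov_inv = np.linalg.pinv(within + 1e-12 * np.eye(within.shape[0]))
    priors = ind.sum(axis=0) / n
    return FDAModel(classes, mean_, directions, centroids, cov_inv, np.log(priors))


def fda_predict(model: FDAModel, matrix) -> np.ndarray:
    return model.predict(np.asarray(matrix, dtype=np.float64))


@dataclass
class MDAModel:
    """Mixture discriminant analysis: per-class Gaussian mixtures, shared covariance."""

    classes: np.ndarray
    means: list                      # per class: (R, p) component means
    weights: list                    # per class: (R,) mixing weights
    cov: np.ndarray                  # shared pooled covariance
    log_priors: np.ndarray
    log_likelihood_trace: list = field(default_factory=list)
    converged: bool = True

    def _log_density(self, x: np.ndarray) -> np.ndarray:
        """(n, g) log of class-conditional mixture densities."""
        p = x.shape[1]
        cov = self.cov + 1e-10 * np.eye(p)
        chol = np.linalg.cholesky(cov)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out = np.empty((x.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            comp = []
            for mu, w in zip(self.means[k], self.weights[k]):
                sol = np.linalg.solve(chol, (x - mu).T)
                maha = (sol ** 2).sum(axis=0)
                comp.append(np.log(max(w, 1e-300))
                            - 0.5 * (maha + logdet + p * np.log(2 * np.pi)))
            out[:, k] = _logsumexp(np.stack(comp), axis=0)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        scores = self._log_density(x) + self.log_priors
        return self.classes[np.argmax(scores, axis=1)]


def _logsumexp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def mda_fit(
    matrix: np.ndarray | pd.DataFrame,
    labels,
    subclasses: int = 3,
    rng_seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MDAModel:
    """Fit MDA by EM: per-class mixtures with a shared pooled covariance.

    Component means are initialised by per-class k-means; EM alternates
    within-class responsibilities and pooled-covariance updates.  The
    log-likelihood trace is recorded and is non-decreasing; if ``max_iter``
    is hit before the tolerance, the best iterate is returned with
    ``converged=False`` and a warning.
    """
    x = np.asarray(matrix, dtype=np.float64)
    y = pd.Series(labels).astype(str).to_numpy()
    classes, y_idx = np.unique(y, return_inverse=True)
    g = len(classes)
    n, p = x.shape
    for k in range(g):
        if (y_idx == k).sum() <= 2 * subclasses:
            raise ValueError(
                f"class {classes[k]!r} has too few samples for {subclasses} subclasses"
            )

    rng = np.random.default_rng(rng_seed)
    means, weights = [], []
    for k in range(g):
        xk = x[y_idx == k]
        if subclasses == 1:
            means.append(xk.mean(axis=0, keepdims=True))
            weights.append(np.ones(1))
        else:
            km = KMeans(n_clusters=subclasses, n_init=3,
                        random_state=int(rng.integers(2 ** 31)))
            km.fit(xk)
            means.append(km.cluster_centers_.copy())
            w = np.bincount(km.labels_, minlength=subclasses).astype(float)
            weights.append(w / w.sum())
    cov = np.atleast_2d(np.cov(x.T)) + 1e-6 * np.eye(p)
    priors = np.bincount(y_idx).astype(float) / n

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(p))
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        new_means = [np.zeros_like(m) for m in means]
        new_weights = [np.zeros_like(w) for w in weights]
        new_cov = np.zeros((p, p))
        ll = 0.0
        for k in range(g):
            xk = x[y_idx == k]
            logc = np.empty((xk.shape[0], len(weights[k])))
            for r, (mu, w) in enumerate(zip(means[k], weights[k])):
                sol = np.linalg.solve(chol, (xk - mu).T)
                logc[:, r] = np.log(max(w, 1e-300)) - 0.5 * (
                    (sol ** 2).sum(axis=0) + logdet + p * np.log(2 * np.pi))
            norm = _logsumexp(logc.T, axis=0)
            ll += float(norm.sum())
            resp = np.exp(logc - norm[:, None])
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            new_weights[k] = nk / nk.sum()
            new_means[k] = (resp.T @ xk) / nk[:, None]
            for r in range(len(nk)):
                d = xk - new_means[k][r]
                new_cov += (resp[:, r:r + 1] * d).T @ d
        new_cov /= n
        trace.append(ll)
        means, weights, cov = new_means, new_weights, new_cov + 1e-9 * np.eye(p)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    if not converged:
        warnings.warn("MDA EM did not converge; returning best iterate")
    return MDAModel(classes, means, weights, cov, np.log(priors), trace, converged)


def mda_predict(model: MDAModel, matrix) -> np.ndarray:
    return model.predict(np.asarray(matrix, dtype=np.float64))


def confusion_matrix(true_labels, predicted_labels) -> pd.DataFrame:
    """Row-normalised confusion matrix (rows = true class, rows sum to 1)."""
    t = pd.Series(true_labels).astype(str)
    p = pd.Series(predicted_labels).astype(str)
    tab = pd.crosstab(t, p)
    classes = sorted(set(tab.index) | set(tab.columns))
    tab = tab.reindex(index=classes, columns=classes, fill_value=0).astype(float)
    return tab.div(tab.sum(axis=1), axis=0)


# ----------------------------------------------------------- simple tests


def groupwise_tests(
    matrix: pd.DataFrame,
    fixed: str | np.ndarray,
    feature_columns: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way F test per feature with Benjamini-Hochberg FDR control."""
    labels = matrix[fixed] if isinstance(fixed, str) else pd.Series(fixed)
    labels = labels.astype(str).to_numpy()
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if feature_columns is None:
        feature_columns = [
            c for c in matrix.columns
            if pd.api.types.is_numeric_dtype(matrix[c]) and c != fixed
        ]
    rows = []
    for c in feature_columns:
        samples = [matrix.loc[labels == gname, c].to_numpy() for gname in groups]
        if all(np.allclose(s, samples[0].mean() if len(samples[0]) else 0) for s in samples):
            f_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = sstats.f_oneway(*samples)
            if not np.isfinite(p):
                f_stat, p = 0.0, 1.0
        row = {"feature": c, "F": float(f_stat), "p": float(p)}
        for gname, s in zip(groups, samples):
            row[f"mean.{gname}"] = float(np.mean(s)) if len(s) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] <= alpha
    return out


def cluster_report(
    clustering: ClusteringResult,
    matrix: pd.DataFrame,
    genotype_column: str = "genotype",
    feature_columns: list[str] | None = None,
    object_counts: np.ndarray | None = None,
    count_threshold: float = 0.0,
    n_exemplars: int = 3,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster genotype composition, mean profile and exemplar IDs."""
    if len(clustering.labels) != len(matrix):
        raise ValueError("clustering and matrix are not aligned")
    if feature_columns is None:
        feature_columns = [c for c in matrix.columns
                           if pd.api.types.is_numeric_dtype(matrix[c])]
    rng = np.random.default_rng(rng_seed)
    rows = []
    ids = matrix["feature_id"] if "feature_id" in matrix else pd.Series(
        np.arange(len(matrix)).astype(str))
    for k in sorted(set(clustering.labels)):
        sel = clustering.labels == k
        sub = matrix.loc[sel]
        comp = sub[genotype_column].value_counts(normalize=True).to_dict() \
            if genotype_column in sub else {}
        pool = ids[sel].to_numpy()
        ex = list(rng.choice(pool, size=min(n_exemplars, len(pool)), replace=False))
        if object_counts is not None:
            has = float(np.mean(np.asarray(object_counts)[sel])) > count_threshold
        else:
            has = bool((sub.get("s.area", pd.Series(dtype=float)) > 0).any())
        row = {"cluster": int(k), "n": int(sel.sum()),
               "has_erbody": has, "exemplars": ";".join(map(str, ex))}
        row.update({f"prop.{g}": p for g, p in comp.items()})
        row.update({f"mean.{c}": float(sub[c].mean()) for c in feature_columns})
        rows.append(row)
    return pd.DataFrame(rows)
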