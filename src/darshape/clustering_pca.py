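"""Ward clustering of DAR metric vectors, the wss-slope heuristic for the
number of clusters, and correlation PCA of the four metrics.

The clustering operates in z-scored metric space. The number of clusters k
is guided by the within-cluster sum of squares wss(k), its slope
s(k) = wss(k+1) - wss(k), and the relative change of slope
f(k) = (s(k-1) - s(k)) / s(k-1); values of k where f(k) is markedly larger
than its preceding neighbor are elbow candidates. PC1 of the correlation
PCA, with all-positive loadings, acts as a composite DAR-size ("extent")
variable; PC2 typically captures openness and PC3 elongation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .errors import DataError
from .path_metrics import METRIC_COLUMNS


@dataclass
class MetricMatrix:
    """Z-scored metric matrix (rows = DARs with no missing metric)."""
    dar_ids: list[str]
    values: np.ndarray           # (n, 4), standardized
    means: np.ndarray            # column means (km) used for z-scoring
    sds: np.ndarray              # column SDs (km, ddof=1)
    n_dropped: int               # rows removed for missing metrics


def make_matrix(metrics: pd.DataFrame, columns: list[str] | None = None) -> MetricMatrix:
    """Drop rows with any missing metric, then z-score each column
    ((x - mean) / sd, sd with ddof=1, matching R's ``scale``)."""
    if len(metrics) == 0:
        raise DataError("empty metrics table")
    columns = columns or METRIC_COLUMNS
    sub = metrics[["dar_id"] + columns].copy()
    ok = sub[columns].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    sub = sub[ok]
    if len(sub) == 0:
        raise DataError("all rows have missing metrics")
    vals = sub[columns].to_numpy(dtype=float)
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1) if len(vals) > 1 else np.zeros(vals.shape[1])
    if np.any(sds == 0):
        bad = [columns[i] for i in np.flatnonzero(sds == 0)]
        raise DataError(f"zero-variance columns cannot be standardized: {bad}")
    return MetricMatrix(sub["dar_id"].tolist(), (vals - means) / sds,
                        means, sds, n_dropped)


def ward_linkage(matrix: MetricMatrix | np.ndarray) -> np.ndarray:
    """Agglomerative tree under Ward's minimum-variance criterion on
    Euclidean distances (the ward.D2 form)."""
    X = matrix.values if isinstance(matrix, MetricMatrix) else np.asarray(matrix, float)
    if len(X) < 2:
        raise DataError("Ward linkage needs at least 2 rows")
    return hierarchy.linkage(X, method="ward")


def cut_tree(tree: np.ndarray, k: int) -> np.ndarray:
    """Labels 1..k, numbered in order of first row occurrence."""
    n = len(tree) + 1
    if not 1 <= k <= n:
        raise DataError(f"k={k} out of range 1..{n}")
    raw = hierarchy.cut_tree(tree, n_clusters=k).ravel()
    return _relabel_first_occurrence(raw)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass
class ClusterCurves:
    """wss(k), slope s(k) = wss(k+1) - wss(k), and relative slope change
    f(k) = (s(k-1) - s(k)) / s(k-1)."""
    wss: dict[int, float]
    s: dict[int, float]
    f: dict[int, float]


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def wss_curve(matrix: MetricMatrix | np.ndarray, tree: np.ndarray,
              k_max: int = 15) -> ClusterCurves:
    """Within-cluster sum of squares for each hierarchical cut k = 1..k_max,
    computed by re-partitioning at each k (standardized space)."""
    X = matrix.values if isinstance(matrix, MetricMatrix) else np.asarray(matrix, float)
    k_max = min(k_max, len(X))
    wss = {k: _wss(X, cut_tree(tree, k)) for k in range(1, k_max + 1)}
    s = {k: wss[k + 1] - wss[k] for k in range(1, k_max)}
    f = {}
    for k in range(2, k_max):
        prev = s.get(k - 1)
        if prev is not None and prev != 0:
            f[k] = (prev - s[k]) / prev
        elif k == 2:
            # s(0) is undefined; by convention f(2) is measured against a
            # flat-slope baseline of 0
            f[k] = 0.0
    return ClusterCurves(wss, s, f)


def curves_from_wss(wss_values: list[float] | dict[int, float]) -> ClusterCurves:
    """Build the s/f curves from a raw wss sequence (k starting at 1)."""
    wss = dict(enumerate(wss_values, start=1)) if not isinstance(wss_values, dict) \
        else dict(wss_values)
    ks = sorted(wss)
    s = {k: wss[k + 1] - wss[k] for k in ks if k + 1 in wss}
    f = {k: (s[k - 1] - s[k]) / s[k - 1]
         for k in ks if k - 1 in s and k in s and s[k - 1] != 0}
    return ClusterCurves(wss, s, f)


def suggest_k(curves: ClusterCurves) -> list[int]:
    """All k whose relative slope change is larger than its preceding
    neighbor's, ranked by f(k) descending. The smallest k with an f value
    (no preceding neighbor) qualifies when its f is positive. The final
    choice of k is the caller's."""
    ks = sorted(curves.f)
    candidates = []
    for k in ks:
        prev = curves.f.get(k - 1)
        fk = curves.f[k]
        if prev is None:
            if fk > 0:
                candidates.append(k)
        elif fk > prev:
            candidates.append(k)
    return sorted(candidates, key=lambda k: -curves.f[k])


class WardClusterer(BaseEstimator, ClusterMixin):
    """Ward hierarchical clustering with the wss-slope elbow heuristic.

    Parameters
    ----------
    n_clusters : cut level k used for ``labels_``.
    k_max : largest k for the wss/s/f curves.

    Attributes (after ``fit``)
    --------------------------
    linkage_ : scipy linkage matrix (the Ward tree).
    labels_ : per-row cluster ids 1..k, numbered by first occurrence.
    curves_ : :class:`ClusterCurves` with the wss/s/f maps.
    suggested_k_ : elbow candidates ranked by f(k) descending.
    """

    def __init__(self, n_clusters: int = 7, k_max: int = 15):
        self.n_clusters = n_clusters
        self.k_max = k_max

    def fit(self, X, y=None):
        X = np.asarray(X.values if isinstance(X, MetricMatrix) else X, dtype=float)
        if X.ndim != 2 or len(X) < 2:
            raise DataError("WardClusterer needs a 2-D matrix with >= 2 rows")
        self.linkage_ = ward_linkage(X)
        self.labels_ = cut_tree(self.linkage_, self.n_clusters)
        self.curves_ = wss_curve(X, self.linkage_, self.k_max)
        self.suggested_k_ = suggest_k(self.curves_)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class DarPCA(BaseEstimator, TransformerMixin):
    """PCA of the four whole-path metrics via a 4x4 eigendecomposition.

    By default the decomposition is of the *covariance* of the raw km
    metrics (all four share the same length unit, so no rescaling is
    needed and PC1 is a genuine composite length). ``scale=True`` switches
    to correlation PCA on z-scored metrics. Components are ordered by
    variance and sign-flipped so each loading vector sums positive; with
    positively covarying length metrics PC1 then has all-positive loadings
    and acts as the composite size ("extent") factor, PC2 is typically
    dominated by net displacement (openness) and PC3 contrasts width with
    the displacement measures (elongation).

    Attributes: ``loadings_`` (columns = components, orthonormal),
    ``explained_variance_ratio_``, ``means_`` (and ``sds_`` when scaled),
    ``interpretation_`` tags.
    """

    def __init__(self, scale: bool = False):
        self.scale = scale

    @staticmethod
    def _as_raw(X) -> np.ndarray:
        """Raw km metric matrix from any accepted container."""
        if isinstance(X, MetricMatrix):
            return X.values * X.sds + X.means
        if isinstance(X, pd.DataFrame):
            cols = [c for c in METRIC_COLUMNS if c in X.columns]
            if len(cols) == len(METRIC_COLUMNS):
                return X[METRIC_COLUMNS].to_numpy(dtype=float)
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y=None):
        X = self._as_raw(X)
        n, p = X.shape
        if n < 3:
            raise DataError("PCA needs at least 3 rows")
        self.means_ = X.mean(axis=0)
        Z = X - self.means_
        if self.scale:
            self.sds_ = X.std(axis=0, ddof=1)
            if np.any(self.sds_ == 0):
                raise DataError("zero-variance column; cannot scale for PCA")
            Z = Z / self.sds_
        cov = (Z.T @ Z) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = np.clip(eigvals[order], 0, None), eigvecs[:, order]
        signs = np.where(eigvecs.sum(axis=0) >= 0, 1.0, -1.0)
        self.loadings_ = eigvecs * signs
        self.explained_variance_ratio_ = eigvals / eigvals.sum()
        self.n_features_in_ = p
        tags = ["extent"]
        for c in range(1, p):
            load = np.abs(self.loadings_[:, c])
            tags.append("openness" if int(np.argmax(load)) == 0 else "elongation")
        self.interpretation_ = tags[:min(p, 3)]
        return self

    def transform(self, X):
        X = self._as_raw(X)
        Z = X - self.means_
        if self.scale:
            Z = Z / self.sds_
        return Z @ self.loadings_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def run_pca(matrix: MetricMatrix, scale: bool = False) -> DarPCA:
    return DarPCA(scale=scale).fit(matrix)


def composite_size(metrics: pd.DataFrame, pca: DarPCA,
                   mode: str = "loading_weighted") -> pd.Series:
    """Nonnegative composite DAR-size score used as the mixed-model response.

    Default: the PC1-loading-weighted combination of the raw (km) metrics —
    nonnegative because loadings and metrics are, so its square root is
    real. Alternative "shifted_score": the centered PC1 score shifted by
    its minimum.
    """
    w = pca.loadings_[:, 0]
    if mode == "loading_weighted":
        if np.any(w < 0):
            raise DataError("PC1 loadings not all positive; composite undefined")
        vals = metrics[METRIC_COLUMNS].to_numpy(dtype=float)
        score = vals @ w
        if np.nanmin(score) < 0:
            raise DataError("negative composite size; inputs violate construction")
        return pd.Series(score, index=metrics.index, name="composite_size")
    if mode == "shifted_score":
        score = pca.transform(metrics[METRIC_COLUMNS])[:, 0]
        score = score - np.nanmin(score)
        return pd.Series(score, index=metrics.index, name="composite_size")
    raise DataError(f"unknown composite-size mode {mode!r}")


def summarize_clusters(labels: np.ndarray, metrics: pd.DataFrame,
                       open_lo_km: float = 0.25, open_hi_km: float = 2.0
                       ) -> pd.DataFrame:
    """Per-cluster n, percent, mean +/- SD of the four metrics (km), an
    openness label from mean net displacement, a transverse flag (mean
    width < mean diameter / 4), and size ranks by mean diameter."""
    df = metrics.copy()
    df["cluster"] = np.asarray(labels)
    rows = []
    n_total = len(df)
    for lab, grp in df.groupby("cluster"):
        row = {"cluster": lab, "n": len(grp),
               "percent": 100.0 * len(grp) / n_total}
        for col in METRIC_COLUMNS:
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_sd"] = grp[col].std(ddof=1)
        net = row["net_displacement_mean"]
        if net < open_lo_km:
            row["openness"] = "closed"
        elif net < open_hi_km:
            row["openness"] = "partially open"
        else:
            row["openness"] = "wide open"
        row["transverse"] = bool(
            row["max_width_mean"] < row["max_diameter_mean"] / 4.0)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    out["size_rank"] = out["max_diameter_mean"].rank(ascending=False, method="min").astype(int)
    return out
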