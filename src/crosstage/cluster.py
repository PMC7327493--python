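"""Medoid clustering with an NB background noise model and outlier detection.

Cells are clustered by k-medoids (PAM with deterministic BUILD
initialization) on the dissimilarity 1 - Pearson correlation of
log2(x + pseudocount) feature-gene profiles.  The cluster number is chosen by
within-cluster dispersion saturation: the smallest k whose relative
improvement when adding one more cluster drops below a tolerance.

A second-order polynomial background model of log2 variance versus log2 mean
across genes parameterizes per-gene negative binomial distributions; a cell
is flagged as an outlier of its cluster when at least ``min_outlier_genes``
genes have an NB tail probability below ``probthr`` (default 1e-4) given the
cluster mean and the background variance.  Outliers are flagged, not
re-clustered, and are excluded from medoid computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import TranscriptCountMatrix


@dataclass
class BackgroundNoiseModel:
    """Polynomial fit log2(var) = a0 + a1*log2(mean) + a2*log2(mean)^2.

    Predicted variance is clamped below at the mean (Poisson floor), keeping
    the implied NB dispersion non-negative over the whole fit domain.
    """

    coefficients: tuple  # (a0, a1, a2)
    domain: tuple  # (min mean, max mean) used in the fit

    def predict_variance(self, mean):
        mean = np.asarray(mean, dtype=float)
        out = np.zeros_like(mean)
        pos = mean > 0
        if pos.any():
            a0, a1, a2 = self.coefficients
            lm = np.log2(mean[pos])
            out[pos] = 2.0 ** (a0 + a1 * lm + a2 * lm**2)
        out = np.maximum(out, mean)
        if np.ndim(out) == 0:
            return float(out)
        return out

    def nb_size(self, mean):
        """NB size parameter r with variance v: r = m^2 / (v - m)."""
        mean = np.asarray(mean, dtype=float)
        var = self.predict_variance(mean)
        excess = np.maximum(var - mean, 1e-12 * np.maximum(mean, 1e-12))
        return mean**2 / excess


def fit_background_model(counts, min_genes: int = 50) -> BackgroundNoiseModel:
    """Fit the mean-variance background model across genes.

    ``counts``: genes x cells normalized transcript counts (DataFrame or
    array).  Genes with zero mean or zero variance are excluded from the fit.
    """
    X = np.asarray(counts, dtype=float)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    ok = (mean > 0) & (var > 0)
    if ok.sum() < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with nonzero mean/variance, got {ok.sum()}"
        )
    lm, lv = np.log2(mean[ok]), np.log2(var[ok])
    if np.unique(lm).size < 3:
        raise ValueError("need >= 3 distinct mean values for a quadratic fit")
    a2, a1, a0 = np.polyfit(lm, lv, deg=2)
    return BackgroundNoiseModel(
        coefficients=(float(a0), float(a1), float(a2)),
        domain=(float(mean[ok].min()), float(mean[ok].max())),
    )


# ---------------------------------------------------------------------------
# k-medoids


def correlation_dissimilarity(
    X, pseudocount: float = 0.1, metric: str = "pearson"
) -> np.ndarray:
    """1 - correlation of log2(x + pseudocount) profiles between samples."""
    L = np.log2(np.asarray(X, dtype=float) + pseudocount)
    if L.shape[0] == 1:
        return np.zeros((1, 1))
    if metric == "spearman":
        L = np.apply_along_axis(stats.rankdata, 1, L)
    elif metric != "pearson":
        raise ValueError("metric must be 'pearson' or 'spearman'")
    with np.errstate(invalid="ignore"):
        # constant profiles yield nan correlations -> treated as 0 (distance 1)
        C = np.corrcoef(L)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _pam(D: np.ndarray, k: int, max_iter: int = 100):
    """PAM with deterministic BUILD init and alternating refinement.

    Ties are broken toward the lowest index.  Returns (labels, medoids, cost);
    the objective (total dissimilarity to assigned medoid) is non-increasing
    over iterations.
    """
    n = D.shape[0]
    k = min(k, n)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = []
        for j in range(len(medoids)):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                new_medoids.append(medoids[j])
                continue
            sub = D[np.ix_(members, members)]
            new_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        new_medoids = sorted(set(new_medoids))
        while len(new_medoids) < len(medoids):  # collapsed medoid: keep old
            for m in medoids:
                if m not in new_medoids:
                    new_medoids.append(m)
                    break
            new_medoids = sorted(new_medoids)
        if new_medoids == medoids:
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(n), np.asarray(medoids)[labels]].sum())
    return labels, np.asarray(medoids), cost


def _nb_tail_probability(x, mean, size):
    """Two-sided NB tail probability, in (0, 1]; small for extreme counts."""
    x = np.asarray(x)
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    size = np.maximum(np.asarray(size, dtype=float), 1e-12)
    p = size / (size + mean)
    lower = stats.nbinom.cdf(x, size, p)
    upper = stats.nbinom.sf(x - 1, size, p)
    return np.minimum(np.minimum(lower, upper) * 2.0, 1.0)


class NBMedoidClustering(BaseEstimator, ClusterMixin):
    """k-medoids clustering of cells with NB-background outlier flagging.

    Parameters
    ----------
    k_max : int
        Largest cluster number scanned.
    saturation_tol : float
        Relative within-dispersion improvement below which adding a cluster
        is considered saturated; the smallest such k is selected.
    probthr : float
        NB tail-probability threshold for outlier gene calls (study setting
        1e-4).
    min_outlier_genes : int
        Number of improbable genes required to flag a cell.
    cthr : int
        Minimum cluster size for downstream lineage analysis (study setting
        15); stored on the model, not enforced here.
    pseudocount : float
        Added before the log transform of the distance computation.

    Attributes (after ``fit`` on a cells x feature-genes array)
    ----------
    labels_, medoid_indices_, outlier_mask_, background_model_,
    n_clusters_, dissimilarity_, within_dispersion_
    """

    def __init__(
        self,
        k_max: int = 10,
        saturation_tol: float = 0.01,
        probthr: float = 1e-4,
        min_outlier_genes: int = 2,
        cthr: int = 15,
        pseudocount: float = 0.1,
        metric: str = "pearson",
        max_iter: int = 100,
        n_clusters: int | None = None,
        k_select: str = "silhouette",
        random_state: int | None = None,
    ):
        self.k_max = k_max
        self.saturation_tol = saturation_tol
        self.probthr = probthr
        self.min_outlier_genes = min_outlier_genes
        self.cthr = cthr
        self.pseudocount = pseudocount
        self.metric = metric
        self.max_iter = max_iter
        self.n_clusters = n_clusters
        self.k_select = k_select
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a 2-D cells x genes array")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        n = X.shape[0]
        D = correlation_dissimilarity(X, self.pseudocount, self.metric)
        self.dissimilarity_ = D

        if self.n_clusters is not None:
            k_star = int(self.n_clusters)
            labels, medoids, cost = _pam(D, k_star, self.max_iter)
            self.within_dispersion_ = {k_star: cost}
        else:
            costs, results = {}, {}
            for k in range(1, min(self.k_max, n) + 1):
                labels, medoids, cost = _pam(D, k, self.max_iter)
                costs[k] = cost
                results[k] = (labels, medoids)
            k_star = self._select_k(D, costs, results)
            labels, medoids = results[k_star]
            self.within_dispersion_ = costs
        self.n_clusters_ = len(medoids)
        self.labels_ = labels

        try:
            self.background_model_ = fit_background_model(X.T, min_genes=3)
        except ValueError:
            # degenerate inputs (e.g. a single cell): no noise model, no outliers
            self.background_model_ = None
        if self.background_model_ is None:
            self.outlier_mask_ = np.zeros(n, dtype=bool)
        else:
            self.outlier_mask_ = self._detect_outliers(X, labels)

        # medoids recomputed over non-outlier members; ties -> lowest index
        final_medoids = []
        for j in range(self.n_clusters_):
            members = np.flatnonzero((labels == j) & ~self.outlier_mask_)
            if members.size == 0:
                members = np.flatnonzero(labels == j)
            sub = D[np.ix_(members, members)]
            final_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        self.medoid_indices_ = np.asarray(final_medoids)
        return self

    def _select_k(self, D, costs, results):
        """Pick the cluster number from the scanned partitions.

        ``silhouette`` (default): largest mean silhouette width over
        k = 2..k_max, falling back to 1 when no partition beats within-noise
        dispersion saturation.  ``saturation``: smallest k whose relative
        within-dispersion improvement when adding a cluster drops below
        ``saturation_tol``.
        """
        ks = sorted(costs)
        if len(ks) == 1:
            return ks[0]
        if costs[1] > 0 and (costs[1] - costs[2]) / costs[1] < self.saturation_tol:
            return 1
        if self.k_select == "saturation":
            for k in ks[:-1]:
                if costs[k] <= 0:
                    return k
                if (costs[k] - costs[k + 1]) / costs[k] < self.saturation_tol:
                    return k
            return ks[-1]
        if self.k_select != "silhouette":
            raise ValueError("k_select must be 'silhouette' or 'saturation'")
        from sklearn.metrics import silhouette_score

        best_k, best_s = ks[-1], -np.inf
        for k in ks[1:]:
            labels = results[k][0]
            if np.unique(labels).size < 2:
                continue
            s = silhouette_score(D, labels, metric="precomputed")
            if s > best_s + 1e-12:
                best_k, best_s = k, s
        return best_k

    def _detect_outliers(self, X, labels):
        if self.probthr <= 0:
            return np.zeros(X.shape[0], dtype=bool)
        noise = self.background_model_
        outlier = np.zeros(X.shape[0], dtype=bool)
        counts = np.round(X).astype(np.int64)
        for j in np.unique(labels):
            members = np.flatnonzero(labels == j)
            if members.size < 2:
                continue
            mean = X[members].mean(axis=0)
            size = noise.nb_size(np.maximum(mean, 1e-12))
            probs = _nb_tail_probability(counts[members], mean[None, :], size[None, :])
            n_extreme = (probs < self.probthr).sum(axis=1)
            outlier[members] = n_extreme >= self.min_outlier_genes
        return outlier

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterModel:
    """Clustering result on a transcript matrix (genes x cells orientation)."""

    labels: pd.Series
    medoids: dict  # cluster id -> medoid cell id
    medoid_profiles: pd.DataFrame  # feature genes x clusters (normalized counts)
    outliers: pd.Series
    noise_model: BackgroundNoiseModel
    probthr: float
    cthr: int
    feature_genes: list = field(default_factory=list)
    within_dispersion: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def eligible_clusters(self):
        """Clusters meeting the minimum size ``cthr`` for lineage analysis."""
        sizes = self.labels.value_counts()
        return sorted(c for c in self.medoids if sizes.get(c, 0) >= self.cthr)


def cluster_cells(
    matrix: TranscriptCountMatrix,
    k_max: int = 10,
    seed: int | None = None,
    **params,
) -> ClusterModel:
    """Cluster the cells of a QC'd transcript matrix.

    Thin wrapper around :class:`NBMedoidClustering` operating on the
    feature-gene submatrix; deterministic (the seed is accepted for API
    symmetry — initialization is deterministic by construction).
    """
    feats = matrix.feature_matrix()
    est = NBMedoidClustering(k_max=k_max, random_state=seed, **params)
    est.fit(feats.values.T)
    cells = matrix.cells
    labels = pd.Series(est.labels_, index=cells, name="cluster")
    medoids = {j: cells[m] for j, m in enumerate(est.medoid_indices_)}
    medoid_profiles = feats[[medoids[j] for j in sorted(medoids)]]
    medoid_profiles.columns = sorted(medoids)
    return ClusterModel(
        labels=labels,
        medoids=medoids,
        medoid_profiles=medoid_profiles,
        outliers=pd.Series(est.outlier_mask_, index=cells, name="is_outlier"),
        noise_model=est.background_model_,
        probthr=est.probthr,
        cthr=est.cthr,
        feature_genes=list(matrix.feature_genes),
        within_dispersion=dict(est.within_dispersion_),
    )


def detect_outliers(
    model: ClusterModel,
    matrix: TranscriptCountMatrix,
    probthr: float | None = None,
    min_outlier_genes: int = 2,
) -> pd.Series:
    """Re-run outlier detection on an existing partition.

    For each cell, per-gene NB tail probabilities are evaluated under the
    cluster mean and the background-model variance; a cell is an outlier iff
    at least ``min_outlier_genes`` genes fall below ``probthr``.
    """
    probthr = model.probthr if probthr is None else probthr
    X = matrix.feature_matrix().values.T
    labels = model.labels.values
    if probthr <= 0:
        return pd.Series(False, index=matrix.cells, name="is_outlier")
    counts = np.round(X).astype(np.int64)
    outlier = np.zeros(X.shape[0], dtype=bool)
    for j in sorted(model.medoids):
        members = np.flatnonzero(labels == j)
        if members.size < 2:
            continue
        mean = X[members].mean(axis=0)
        size = model.noise_model.nb_size(np.maximum(mean, 1e-12))
        probs = _nb_tail_probability(counts[members], mean[None, :], size[None, :])
        outlier[members] = (probs < probthr).sum(axis=1) >= min_outlier_genes
    return pd.Series(outlier, index=matrix.cells, name="is_outlier")
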