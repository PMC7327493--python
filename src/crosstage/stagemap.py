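"""Quadratic-programming projection of query cells onto reference medoids.

Each query cell profile x (over the shared feature genes) is expressed as a
convex combination of reference cluster medoid profiles M:

    w* = argmin ||x - M w||^2   subject to   w >= 0,  sum(w) = 1

The weight vector w lives on the probability simplex, so each component is
directly interpretable as the similarity of the query cell to one reference
cluster (the per-cluster "classifier" weights on a 0-1 scale).  The solver is
a primal active-set method for the strictly convex QP obtained after a tiny
ridge regularization; it terminates finitely and deterministically, and the
solution is certified by the KKT conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import TranscriptCountMatrix
from .cluster import ClusterModel


def shared_features(features_A, features_B, min_genes: int = 10):
    """Sorted intersection of the two datasets' feature-gene sets."""
    inter = sorted(set(features_A) & set(features_B))
    if len(inter) < min_genes:
        raise ValueError(
            f"shared feature set too small ({len(inter)} < {min_genes} genes)"
        )
    return inter


def _solve_simplex_qp(Q: np.ndarray, c: np.ndarray, max_iter: int = 200):
    """min 1/2 w'Qw - c'w  s.t.  sum(w)=1, w>=0, for symmetric PD Q.

    Primal active-set method: starting from the uniform feasible point,
    repeatedly solve the equality-constrained subproblem on the free set,
    step to the first blocking bound, and release the most negative
    multiplier until the KKT conditions hold.  Deterministic; ties broken
    toward the lowest index.
    """
    k = Q.shape[0]
    w = np.full(k, 1.0 / k)
    free = np.ones(k, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(free)
        nf = idx.size
        KKT = np.zeros((nf + 1, nf + 1))
        KKT[:nf, :nf] = Q[np.ix_(idx, idx)]
        KKT[:nf, nf] = 1.0
        KKT[nf, :nf] = 1.0
        rhs = np.concatenate([c[idx], [1.0]])
        sol = np.linalg.solve(KKT, rhs)
        w_new = np.zeros(k)
        w_new[idx] = sol[:nf]
        if (w_new[idx] >= -1e-12).all():
            w = w_new
            # dual feasibility: on the free set the gradient equals the
            # multiplier lambda; bound components need g_i - lambda >= 0
            g = Q @ w - c
            lam = g[idx].mean()
            bound = np.flatnonzero(~free)
            if bound.size == 0:
                return w, lam
            slack = g[bound] - lam
            worst = np.argmin(slack)
            if slack[worst] >= -1e-9:
                return w, lam
            free[bound[worst]] = True
        else:
            # step toward w_new until the first free component hits zero
            d = w_new - w
            blocking = idx[(w_new[idx] < -1e-12) & (d[idx] < 0)]
            alphas = -w[blocking] / d[blocking]
            j = blocking[np.argmin(alphas)]
            alpha = max(min(alphas.min(), 1.0), 0.0)
            w = w + alpha * d
            w[j] = 0.0
            free[j] = False
            if not free.any():  # numerical corner: restart from best vertex
                free[np.argmax(c - 0.5 * np.diag(Q))] = True
    raise RuntimeError("simplex QP active-set did not converge")


def project_cell(x, M, ridge: float = 1e-10):
    """Project one query profile onto the simplex span of medoid columns.

    ``M`` is genes x medoids.  Returns ``(w, residual)`` with residual
    ``||x - M w*||^2``.
    """
    x = np.asarray(x, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or x.shape[0] != M.shape[0]:
        raise ValueError("x and M have incompatible shapes")
    if not (np.isfinite(x).all() and np.isfinite(M).all()):
        raise ValueError("non-finite entries in projection input")
    k = M.shape[1]
    if k == 1:
        w = np.ones(1)
        return w, float(np.sum((x - M[:, 0]) ** 2))
    Q = M.T @ M
    scale = max(np.trace(Q) / k, 1.0)
    Q = Q + ridge * scale * np.eye(k)
    c = M.T @ x
    w, _ = _solve_simplex_qp(Q, c)
    w = np.maximum(w, 0.0)
    w = w / w.sum()
    resid = float(np.sum((x - M @ w) ** 2))
    return w, resid


def kkt_residual(x, M, w, ridge: float = 1e-10):
    """KKT violation of a candidate solution (for certification in tests).

    Returns the maximum of: simplex infeasibility, spread of the gradient
    over active components, and dual infeasibility of inactive components.
    """
    x = np.asarray(x, dtype=float)
    M = np.asarray(M, dtype=float)
    w = np.asarray(w, dtype=float)
    k = M.shape[1]
    Q = M.T @ M
    scale = max(np.trace(Q) / k, 1.0)
    g = (Q + ridge * scale * np.eye(k)) @ w - M.T @ x
    active = w > 1e-8
    feas = abs(w.sum() - 1.0) + max(0.0, -(w.min()))
    if active.any():
        lam = g[active].mean()
        spread = np.abs(g[active] - lam).max() if active.sum() > 1 else 0.0
        dual = max(0.0, (lam - g[~active]).max()) if (~active).any() else 0.0
    else:
        spread, dual = np.inf, np.inf
    return max(feas, spread, dual)


class MedoidProjector(BaseEstimator, TransformerMixin):
    """scikit-learn transformer: query cells -> simplex weights over medoids.

    ``fit`` takes the reference medoid profiles as an n_medoids x n_genes
    array (scikit-learn samples x features orientation); ``transform`` maps
    query cells (cells x genes over the same genes) to a cells x n_medoids
    weight matrix whose rows lie on the probability simplex.
    """

    def __init__(self, ridge: float = 1e-10):
        self.ridge = ridge

    def fit(self, X, y=None):
        M = np.asarray(X, dtype=float)
        if M.ndim != 2 or M.shape[0] < 1:
            raise ValueError("need at least one medoid profile")
        if (np.abs(M).sum(axis=1) == 0).any():
            raise ValueError("all-zero medoid profile")
        self.medoids_ = M
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        M = self.medoids_.T  # genes x medoids
        k = self.medoids_.shape[0]
        W = np.zeros((X.shape[0], k))
        residuals = np.zeros(X.shape[0])
        flagged = np.zeros(X.shape[0], dtype=bool)
        for i, x in enumerate(X):
            if np.abs(x).sum() == 0:
                W[i] = 1.0 / k
                flagged[i] = True
                continue
            W[i], residuals[i] = project_cell(x, M, ridge=self.ridge)
        self.residuals_ = residuals
        self.flagged_uniform_ = flagged
        return W


@dataclass
class MappingWeights:
    """Per-query-cell simplex weights over the reference clusters."""

    weights: pd.DataFrame  # query cells x reference clusters
    residuals: pd.Series
    flagged_uniform: pd.Series
    shared_genes: list = field(default_factory=list)

    def argmax_cluster(self) -> pd.Series:
        return self.weights.idxmax(axis=1)

    def cluster_weight_map(self, cluster) -> pd.Series:
        """Weights of one reference cluster over all query cells (0-1 scale),
        exportable for coloring an external embedding."""
        return self.weights[cluster]


def map_dataset(
    query: TranscriptCountMatrix,
    reference: ClusterModel,
    reference_features=None,
    log_space: bool = False,
    pseudocount: float = 0.1,
) -> MappingWeights:
    """Project every query cell onto the reference cluster medoids.

    The shared feature set is the intersection of the query's feature genes
    with the reference's; medoid and query profiles are taken in linear
    normalized space by default (``log_space`` transforms both sides by
    log2(x + pseudocount)).
    """
    ref_feats = (
        list(reference_features)
        if reference_features is not None
        else list(reference.feature_genes)
    )
    genes = shared_features(query.feature_genes, ref_feats)
    M = reference.medoid_profiles.loc[genes]
    X = query.counts.loc[genes]
    if log_space:
        M = np.log2(M + pseudocount)
        X = np.log2(X + pseudocount)
    proj = MedoidProjector().fit(M.values.T)
    W = proj.transform(X.values.T)
    clusters = list(reference.medoid_profiles.columns)
    weights = pd.DataFrame(W, index=query.cells, columns=clusters)
    return MappingWeights(
        weights=weights,
        residuals=pd.Series(proj.residuals_, index=query.cells, name="residual"),
        flagged_uniform=pd.Series(
            proj.flagged_uniform_, index=query.cells, name="uniform_fallback"
        ),
        shared_genes=genes,
    )
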