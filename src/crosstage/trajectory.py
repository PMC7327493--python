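"""Lineage links, transcriptome entropy, pseudotime and SOM gene modules.

Lineage structure between clusters is inferred geometrically: each cell is
projected onto the line segments joining its cluster medoid to every other
medoid (in log feature space) and assigned to the link with the largest
positive projection.  A link's score is the fraction of the two flanking
clusters' cells assigned to it, and its significance is a binomial tail
against a null in which a cell lands on any given link with probability
1/(2*(k-1)) — the projection sign is symmetric and the target cluster
uniform among the k-1 alternatives.  Only clusters with at least ``cthr``
cells (study setting 15) enter the graph, and links with p < ``pthr``
(study setting 0.01) are significant.

Cells of a user-specified cluster chain are ordered pseudo-temporally by
(chain position, projection coordinate along the chain direction), per-gene
profiles are smoothed by local quadratic regression with tricube weights,
and co-regulated gene modules are extracted from a 1-D self-organizing map
of the z-score-transformed pseudo-temporal profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cluster import ClusterModel
from .containers import TranscriptCountMatrix


def compute_entropy(profile) -> float:
    """Shannon entropy (nats) of a cell's transcriptome composition."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("profile must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("profile total must be positive")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class LineageGraph:
    """Cluster-level lineage graph with link scores and p-values."""

    nodes: pd.DataFrame  # cluster, size, median_entropy
    edges: pd.DataFrame  # cluster_a, cluster_b, n_on, score, pval, significant
    pthr: float = 0.01
    pethr: float = 0.05
    scthr: float = 0.6

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]


def _log_feature_space(matrix: TranscriptCountMatrix, pseudocount: float = 0.1):
    feats = matrix.feature_matrix()
    return np.log2(feats.values.T + pseudocount)  # cells x genes


def infer_lineage_links(
    model: ClusterModel,
    matrix: TranscriptCountMatrix,
    pthr: float = 0.01,
    pethr: float = 0.05,
    scthr: float = 0.6,
    pseudocount: float = 0.1,
) -> LineageGraph:
    """Build the medoid-link lineage graph over eligible clusters."""
    eligible = model.eligible_clusters()
    if len(eligible) < 2:
        raise ValueError("need >= 2 clusters of size >= cthr for lineage links")
    Y = _log_feature_space(matrix, pseudocount)
    cells = list(matrix.cells)
    cell_pos = {c: i for i, c in enumerate(cells)}
    med = {c: Y[cell_pos[model.medoids[c]]] for c in eligible}
    k = len(eligible)

    counts_all = matrix.counts.values
    node_rows = []
    for c in eligible:
        members = model.labels.index[model.labels == c]
        ent = [compute_entropy(counts_all[:, cell_pos[m]]) for m in members]
        node_rows.append((c, len(members), float(np.median(ent))))
    nodes = pd.DataFrame(node_rows, columns=["cluster", "size", "median_entropy"])

    on_link = {}  # frozenset({a, b}) -> cell count
    assigned = {c: 0 for c in eligible}
    for a in eligible:
        members = [cell_pos[c] for c in model.labels.index[model.labels == a]]
        dirs, targets = [], []
        for b in eligible:
            if b == a:
                continue
            d = med[b] - med[a]
            nrm = float(d @ d)
            if nrm == 0:
                warnings.warn(f"coincident medoids for clusters {a} and {b}; link skipped")
                continue
            dirs.append(d / nrm)
            targets.append(b)
        if not dirs:
            continue
        Dm = np.stack(dirs)  # links x genes, scaled so u = Dm @ (y - med_a)
        U = (Y[members] - med[a]) @ Dm.T  # cells x links
        best = np.argmax(U, axis=1)
        upos = U[np.arange(len(members)), best] > 0
        for i in np.flatnonzero(upos):
            key = frozenset((a, targets[best[i]]))
            on_link[key] = on_link.get(key, 0) + 1
            assigned[a] += 1

    p0 = 1.0 / (2.0 * (k - 1))
    sizes = dict(zip(nodes["cluster"], nodes["size"]))
    rows = []
    for key, n_on in sorted(on_link.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        n_flank = sizes[a] + sizes[b]
        score = n_on / n_flank
        pval = float(stats.binom.sf(n_on - 1, n_flank, p0))
        pval = min(max(pval, np.finfo(float).tiny), 1.0)
        rows.append((a, b, n_on, score, pval, pval < pthr))
    edges = pd.DataFrame(
        rows,
        columns=["cluster_a", "cluster_b", "n_on", "score", "pval", "significant"],
    )
    return LineageGraph(nodes=nodes, edges=edges, pthr=pthr, pethr=pethr, scthr=scthr)


# ---------------------------------------------------------------------------
# pseudotime ordering and smoothing


@dataclass
class TrajectoryResult:
    """Ordered chain cells with smoothed pseudo-temporal gene profiles."""

    chain: list
    cell_order: list
    pseudotime: pd.Series  # rank / (n-1) in [0, 1]
    smoothed: pd.DataFrame  # genes x ordered cells
    som_nodes: pd.Series | None = None
    modules: pd.Series | None = None


def loess_smooth(y: np.ndarray, x: np.ndarray | None = None, span: float = 0.75):
    """Local quadratic regression with tricube weights (loess).

    ``y`` may be 1-D or genes x positions; smoothing runs along the last
    axis.  The bandwidth at each point covers ``span`` of the data.
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    n = Y.shape[1]
    if x is None:
        x = np.linspace(0.0, 1.0, n)
    x = np.asarray(x, dtype=float)
    r = max(int(np.ceil(span * n)), 4)
    r = min(r, n)
    V = np.stack([np.ones(n), x, x**2], axis=1)  # n x 3
    out = np.empty_like(Y)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, r - 1)[r - 1]
        h = h if h > 0 else 1.0
        wgt = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        Vw = V * wgt[:, None]
        A = V.T @ Vw  # 3 x 3
        B = Vw.T @ Y.T  # 3 x genes
        try:
            beta = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, B, rcond=None)[0]
        out[:, i] = beta[0] + beta[1] * x[i] + beta[2] * x[i] ** 2
    return out[0] if np.ndim(y) == 1 else out


def pseudotime_order(
    matrix: TranscriptCountMatrix,
    chain,
    model: ClusterModel,
    genes=None,
    span: float = 0.75,
    pseudocount: float = 0.1,
) -> TrajectoryResult:
    """Order the cells of a cluster chain pseudo-temporally and smooth genes.

    Within a cluster, cells are ordered by their projection onto the local
    chain direction (next minus previous medoid for interior clusters);
    reversing the chain reverses the order exactly.  Ties break by cell
    index.  Smoothed profiles are loess fits of log2(x + pseudocount) over
    the normalized rank.
    """
    chain = list(chain)
    if not chain:
        raise ValueError("empty cluster chain")
    missing = [c for c in chain if c not in model.medoids]
    if missing:
        raise ValueError(f"chain clusters absent from the model: {missing}")
    Y = _log_feature_space(matrix, pseudocount)
    cells = list(matrix.cells)
    cell_pos = {c: i for i, c in enumerate(cells)}
    med = {c: Y[cell_pos[model.medoids[c]]] for c in chain}

    order_keys = []
    for pos_i, c in enumerate(chain):
        if len(chain) == 1:
            direction = None
        else:
            prev_c = chain[pos_i - 1] if pos_i > 0 else None
            next_c = chain[pos_i + 1] if pos_i < len(chain) - 1 else None
            if prev_c is None:
                d = med[next_c] - med[c]
            elif next_c is None:
                d = med[c] - med[prev_c]
            else:
                d = med[next_c] - med[prev_c]
            nrm = float(d @ d)
            direction = d / nrm if nrm > 0 else None
        members = [m for m in model.labels.index[model.labels == c]]
        for m in members:
            u = (
                float((Y[cell_pos[m]] - med[c]) @ direction)
                if direction is not None
                else 0.0
            )
            order_keys.append((pos_i, u, cell_pos[m], m))
    order_keys.sort(key=lambda t: (t[0], t[1], t[2]))
    cell_order = [t[3] for t in order_keys]
    n = len(cell_order)
    pt = pd.Series(
        np.arange(n) / max(n - 1, 1), index=cell_order, name="pseudotime"
    )

    gene_list = list(genes) if genes is not None else list(matrix.feature_genes)
    prof = np.log2(matrix.counts.loc[gene_list, cell_order].values + pseudocount)
    smoothed = loess_smooth(prof, span=span)
    smoothed = pd.DataFrame(smoothed, index=gene_list, columns=cell_order)
    return TrajectoryResult(
        chain=chain, cell_order=cell_order, pseudotime=pt, smoothed=smoothed
    )


# ---------------------------------------------------------------------------
# 1-D self-organizing map and gene modules


class SOM1D(BaseEstimator):
    """One-dimensional self-organizing map over profile vectors.

    Prototypes are initialized by linear interpolation along the first
    principal component (a deterministic, topology-respecting start) and
    refined by seeded online training with linearly decaying learning rate
    and Gaussian neighborhood.
    """

    def __init__(
        self,
        n_nodes: int = 50,
        n_epochs: int = 2000,
        learning_rate: float = 0.5,
        final_learning_rate: float = 0.01,
        random_state: int = 0,
    ):
        self.n_nodes = n_nodes
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.final_learning_rate = final_learning_rate
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        center = X.mean(axis=0)
        Xc = X - center
        # first principal component via SVD; deterministic sign convention
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Vt[0]
        if pc1[np.argmax(np.abs(pc1))] < 0:
            pc1 = -pc1
        coords = Xc @ pc1
        lo, hi = coords.min(), coords.max()
        alphas = np.linspace(lo, hi, self.n_nodes)
        proto = center[None, :] + alphas[:, None] * pc1[None, :]

        sigma0 = max(self.n_nodes / 4.0, 1.0)
        sigma1 = 0.5
        node_idx = np.arange(self.n_nodes)
        total = self.n_epochs
        for epoch in range(total):
            frac = epoch / max(total - 1, 1)
            lr = self.learning_rate + frac * (self.final_learning_rate - self.learning_rate)
            sigma = sigma0 + frac * (sigma1 - sigma0)
            for i in rng.permutation(n):
                bmu = int(np.argmin(((proto - X[i]) ** 2).sum(axis=1)))
                h = np.exp(-0.5 * ((node_idx - bmu) / sigma) ** 2)
                proto += lr * h[:, None] * (X[i] - proto)
        self.prototypes_ = proto
        self.labels_ = self.predict(X)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.prototypes_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def som_modules(
    smoothed: pd.DataFrame,
    n_nodes: int = 50,
    merge_correlation: float = 0.85,
    n_epochs: int = 2000,
    random_state: int = 0,
):
    """Group genes into co-regulation modules via a 1-D SOM.

    Profiles are z-score transformed across pseudotime, mapped onto a 1-D
    SOM, and adjacent occupied nodes whose prototypes correlate above
    ``merge_correlation`` are merged into one module (maximal merged runs).
    Returns a DataFrame indexed by gene with columns node and module.
    """
    X = smoothed.values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).all():
        raise ValueError("all profiles are constant; no modules to extract")
    Z = (X - mu) / np.where(sd == 0, 1.0, sd)

    if Z.shape[0] == 1:
        return pd.DataFrame({"node": [0], "module": [0]}, index=smoothed.index)

    som = SOM1D(
        n_nodes=min(n_nodes, max(Z.shape[0], 2)),
        n_epochs=n_epochs,
        random_state=random_state,
    ).fit(Z)
    nodes = som.labels_
    occupied = sorted(set(nodes))
    proto = som.prototypes_

    module_of_node = {}
    module = 0
    for i, nd in enumerate(occupied):
        if i == 0:
            module_of_node[nd] = module
            continue
        prev = occupied[i - 1]
        a, b = proto[prev], proto[nd]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(a, b)[0, 1]
        corr = 0.0 if np.isnan(corr) else corr
        if corr <= merge_correlation:
            module += 1
        module_of_node[nd] = module
    return pd.DataFrame(
        {"node": nodes, "module": [module_of_node[nd] for nd in nodes]},
        index=smoothed.index,
    )


def zscore_profiles(smoothed: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score transform of pseudo-temporal profiles."""
    X = smoothed.values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(Z, index=smoothed.index, columns=smoothed.columns)
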