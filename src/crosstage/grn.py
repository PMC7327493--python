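"""Random-forest gene regulatory network inference (GENIE3-style).

For every target gene, a random forest regresses the target's standardized
expression on all other (candidate regulator) genes; the importance of a
regulator for a target is its total variance-reduction importance in that
forest, normalized per target to sum to one.  Edges are pooled over targets,
ranked by weight (ties broken lexicographically by regulator then target)
and truncated to the top-N list.  Gene filters follow the study settings:
fetal profile keeps genes expressed at > 4 transcripts in at least two
cells (top 1,000 edges), adult at > 5 transcripts in at least one cell
(top 1,500 edges).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor


@dataclass
class GrnConfig:
    """Gene filter and forest settings for network inference."""

    min_transcripts: float = 4.0
    min_cells: int = 2
    n_trees: int = 1000
    max_features: str | float = "sqrt"
    top_edges: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.top_edges < 1:
            raise ValueError("top_edges must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


GRN_PROFILES = {
    "fetal": dict(min_transcripts=4, min_cells=2, top_edges=1000),
    "adult": dict(min_transcripts=5, min_cells=1, top_edges=1500),
}


def grn_profile(name: str, **overrides) -> GrnConfig:
    if name not in GRN_PROFILES:
        raise KeyError(f"unknown GRN profile {name!r}")
    return replace(GrnConfig(**GRN_PROFILES[name]), **overrides)


def filter_grn_genes(counts: pd.DataFrame, config: GrnConfig):
    """Genes expressed strictly above the threshold in enough cells."""
    keep = (counts.values > config.min_transcripts).sum(axis=1) >= config.min_cells
    genes = list(counts.index[keep])
    if not genes:
        raise ValueError("no genes pass the GRN expression filter")
    return genes


class GRNForest:
    """Per-target random forests pooled into a ranked edge list.

    scikit-learn-style: ``fit`` on a cells x genes matrix with gene names,
    fitted attribute ``edges_`` (regulator, target, weight, rank).  Cells are
    sorted canonically before fitting so edge weights are invariant to the
    input cell order under a fixed seed.
    """

    def __init__(self, config: GrnConfig | None = None):
        self.config = config or GrnConfig()

    def fit(self, counts: pd.DataFrame):
        cfg = self.config
        counts = counts.sort_index(axis=1)  # canonical cell order
        genes = list(counts.index)
        if len(genes) < 3:
            raise ValueError("need >= 3 genes for network inference")
        if counts.shape[1] < 10:
            raise ValueError("need >= 10 cells for network inference")
        X_all = counts.values.T.astype(float)  # cells x genes
        rows = []
        for t_idx, target in enumerate(genes):
            y = X_all[:, t_idx]
            sd = y.std()
            if sd == 0:
                continue  # constant target contributes no edges
            y = (y - y.mean()) / sd
            predictors = [g for g in range(len(genes)) if g != t_idx]
            X = X_all[:, predictors]
            forest = RandomForestRegressor(
                n_estimators=cfg.n_trees,
                max_features=cfg.max_features,
                random_state=(cfg.seed * 1000003 + t_idx) % (2**31 - 1),
                n_jobs=1,
            )
            forest.fit(X, y)
            imp = forest.feature_importances_
            for j, g in enumerate(predictors):
                if imp[j] > 0:
                    rows.append((genes[g], target, float(imp[j])))
        edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
        edges = edges.sort_values(
            ["weight", "regulator", "target"], ascending=[False, True, True]
        ).reset_index(drop=True)
        edges["rank"] = np.arange(1, len(edges) + 1)
        self.edges_ = edges.head(cfg.top_edges).reset_index(drop=True)
        return self


def infer_grn(counts: pd.DataFrame, config: GrnConfig | None = None) -> pd.DataFrame:
    """Rank regulator -> target edges from a filtered expression matrix."""
    return GRNForest(config).fit(counts).edges_


def extract_modules(edges: pd.DataFrame):
    """Connected components of the undirected top-N edge graph.

    Returns a list of gene sets, largest first (ties by sorted members).
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    g = nx.Graph()
    for r in edges.itertuples(index=False):
        g.add_edge(r.regulator, r.target)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def module_scores(counts: pd.DataFrame, modules) -> pd.DataFrame:
    """Aggregated expression per module: mean member z-score per cell."""
    X = counts.values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd == 0, 1.0, sd)
    zdf = pd.DataFrame(Z, index=counts.index, columns=counts.columns)
    rows = {}
    for i, members in enumerate(modules):
        present = [g for g in members if g in zdf.index]
        if present:
            rows[f"module_{i}"] = zdf.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T
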