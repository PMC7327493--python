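"""Cell and gene QC cascade with downscaling normalization.

Cells are removed when their total corrected transcript count falls below
``mintotal`` (strict inequality: a cell at exactly the threshold is kept) or
when the fraction of *Kcnq1ot1* — a marker of low-quality cells — strictly
exceeds ``kcnq_fraction``.  Retained cells are normalized by downscaling to a
common reference total.  The downstream feature-gene set excludes ribosomal
subunit genes, predicted genes with a Gm identifier, ERCC spike-ins, an
explicit exclusion list (``fgenes``), and all genes correlating with any
``cgenes`` anchor (Pearson r strictly above ``kcnq_corr``) — the mechanism
used to strip cell-cycle- and batch-associated variability.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import TranscriptCountMatrix

CGENES_FETAL = (
    "Malat1", "Xist", "Pcna", "Mki67", "Mir703", "Ptma", "Actb",
    "Hsp90aa1", "Hsp90ab1", "Ppia", "H19",
)
CGENES_ADULT = (
    "Pcna", "Mki67", "Mir703", "Gm44044", "Gm22757", "Gm4775", "Gm17541",
    "Gm8225", "Gm8730", "Ptma", "Actb", "Hsp90aa1", "Hsp90ab1", "Ppia",
)


@dataclass
class QcConfig:
    """Thresholds and gene lists of the QC cascade."""

    mintotal: float = 2500.0
    kcnq_fraction: float = 0.02
    kcnq_corr: float = 0.65
    kcnq_gene: str = "Kcnq1ot1"
    fgenes: tuple = ("Malat1", "Xist")
    cgenes: tuple = CGENES_FETAL
    exclude_patterns: tuple = (r"^Rp[sl]\d", r"^Gm\d+$", r"^ERCC-")
    pseudocount: float = 0.1
    downscale_reference: str = "min"  # "min" or "median"

    def __post_init__(self):
        if self.mintotal <= 0:
            raise ValueError("mintotal must be > 0")
        if not 0 < self.kcnq_fraction < 1:
            raise ValueError("kcnq_fraction must be in (0, 1)")
        if not 0 < self.kcnq_corr < 1:
            raise ValueError("kcnq_corr must be in (0, 1)")


#: Dataset-specific total-transcript thresholds used in the study design.
DEFAULT_PROFILES = {
    "fetal_thymus": dict(mintotal=2500, cgenes=CGENES_FETAL),
    "adult_thymus": dict(mintotal=2500, cgenes=CGENES_ADULT),
    "fetal_frozen": dict(mintotal=1500),
    "adult_frozen": dict(mintotal=1000),
    "blood": dict(mintotal=800),
    "lymph_combined": dict(mintotal=500),
    "stimulated": dict(mintotal=500),
}


def qc_profile(name: str, **overrides) -> QcConfig:
    """A named dataset profile as a :class:`QcConfig`."""
    if name not in DEFAULT_PROFILES:
        raise KeyError(f"unknown QC profile {name!r}; options: {sorted(DEFAULT_PROFILES)}")
    return replace(QcConfig(**DEFAULT_PROFILES[name]), **overrides)


def filter_cells(counts: pd.DataFrame, config: QcConfig):
    """Apply the cell filters on corrected (pre-normalization) counts.

    Returns ``(retained_cells, report)``; the report lists per cell its
    total, Kcnq1ot1 fraction, status and removal reason.  A cell failing
    both filters is reported under ``low_total`` (deterministic precedence).
    """
    totals = counts.sum(axis=0)
    if config.kcnq_gene in counts.index:
        with np.errstate(invalid="ignore", divide="ignore"):
            kcnq_frac = (counts.loc[config.kcnq_gene] / totals).fillna(0.0)
    else:
        warnings.warn(
            f"{config.kcnq_gene} absent from gene ids; fraction filter skipped"
        )
        kcnq_frac = pd.Series(0.0, index=counts.columns)
    low_total = totals < config.mintotal
    high_kcnq = kcnq_frac > config.kcnq_fraction
    reason = pd.Series("", index=counts.columns)
    reason[high_kcnq] = "high_kcnq"
    reason[low_total] = "low_total"  # precedence: total filter reported first
    removed = low_total | high_kcnq
    report = pd.DataFrame(
        {
            "total": totals,
            "kcnq_fraction": kcnq_frac,
            "status": np.where(removed, "removed", "retained"),
            "reason": reason,
        }
    )
    return counts.columns[~removed], report


def remove_correlated_genes(
    counts: pd.DataFrame, anchor_genes, corr_threshold: float = 0.65
):
    """Genes to drop from the feature set: anchors plus their correlates.

    A gene is dropped iff its Pearson correlation with any anchor across the
    retained cells is strictly greater than ``corr_threshold``; zero-variance
    genes have correlation treated as 0.  Returns the set of dropped genes.
    """
    anchors = [g for g in anchor_genes if g in counts.index]
    if not anchors:
        return set()
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 cells for correlation filtering")
    X = counts.values
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = Xc / sd_safe[:, None]
    anchor_pos = [counts.index.get_loc(g) for g in anchors]
    corr = Z @ Z[anchor_pos].T / X.shape[1]
    corr[sd == 0, :] = 0.0
    corr[:, np.array(sd[anchor_pos]) == 0] = 0.0
    hit = (corr > corr_threshold).any(axis=1)
    dropped = set(counts.index[hit]) | set(anchors)
    return dropped


def normalize_downscale(counts: pd.DataFrame, reference: str = "min"):
    """Scale every cell to a common reference total (downscaling).

    Returns ``(normalized, totals, reference_total)``.  Within-cell gene
    proportions are preserved exactly.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total cells cannot be normalized: {bad[:5]}")
    if reference == "min":
        ref = float(totals.min())
    elif reference == "median":
        ref = float(totals.median())
    else:
        raise ValueError("reference must be 'min' or 'median'")
    normalized = counts * (ref / totals)
    return normalized, totals, ref


def select_features(counts: pd.DataFrame, config: QcConfig, dropped_correlates=None):
    """The feature-gene set used for distances and the QP projection."""
    patterns = [re.compile(p) for p in config.exclude_patterns]
    dropped_correlates = dropped_correlates or set()
    features = [
        g
        for g in counts.index
        if g not in config.fgenes
        and g not in dropped_correlates
        and not any(p.search(str(g)) for p in patterns)
    ]
    if not features:
        raise ValueError("feature-gene set is empty after exclusions")
    return features


def run_qc(counts: pd.DataFrame, config: QcConfig | None = None):
    """Full cascade: cell filters -> downscaling -> feature selection.

    ``counts`` are corrected transcript counts (genes x cells).  Returns
    ``(TranscriptCountMatrix, report)``.
    """
    config = config or QcConfig()
    retained, report = filter_cells(counts, config)
    if len(retained) == 0:
        raise ValueError("no cells retained by the QC filters")
    kept = counts[retained]
    normalized, totals, ref = normalize_downscale(
        kept, reference=config.downscale_reference
    )
    anchors = tuple(config.cgenes) + (config.kcnq_gene,)
    dropped = remove_correlated_genes(kept, anchors, config.kcnq_corr)
    features = select_features(normalized, config, dropped_correlates=dropped)
    tcm = TranscriptCountMatrix(
        counts=normalized,
        pre_filter_totals=counts.sum(axis=0),
        reference_total=ref,
        feature_genes=features,
    )
    return tcm, report


class DownscaleNormalizer(BaseEstimator, TransformerMixin):
    """scikit-learn transformer scaling each sample (cell) to a common total.

    Operates on cells x genes arrays (scikit-learn orientation).  The
    reference total is learned from the data seen in ``fit``.
    """

    def __init__(self, reference: str = "min"):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("zero-total samples cannot be normalized")
        self.reference_total_ = (
            float(np.min(totals)) if self.reference == "min" else float(np.median(totals))
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("zero-total samples cannot be normalized")
        return X * (self.reference_total_ / totals)
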