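"""Shared in-memory containers for the pipeline stages.

Matrices follow the genes x cells orientation throughout (the convention of
plate-based scRNA-seq count tables); estimator classes that follow the
scikit-learn API transpose to cells x genes internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Number of distinct 6 nt unique molecular identifiers, 4**6.
UMI_SPACE = 4096


@dataclass
class UmiCountMatrix:
    """Raw genes x cells matrix of distinct-UMI counts with cell metadata.

    Every entry is the number of distinct UMIs observed for a (gene, cell)
    pair and is therefore bounded by the UMI space size ``umi_space``.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame = None
    umi_space: int = UMI_SPACE
    spike_genes: tuple = ()

    def __post_init__(self):
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("UMI counts must be non-negative")
        if (self.counts.values > self.umi_space).any():
            raise ValueError(
                f"UMI count exceeds UMI space size K={self.umi_space}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns


@dataclass
class TranscriptCountMatrix:
    """Collision-corrected, downscaled counts for QC-retained cells.

    ``counts`` holds normalized transcript counts (genes x retained cells);
    ``pre_filter_totals`` the per-cell totals before filtering, and
    ``feature_genes`` the gene set used downstream for distances and the
    quadratic-programming projection.
    """

    counts: pd.DataFrame
    pre_filter_totals: pd.Series
    reference_total: float
    feature_genes: list = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    def feature_matrix(self) -> pd.DataFrame:
        return self.counts.loc[list(self.feature_genes)]
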