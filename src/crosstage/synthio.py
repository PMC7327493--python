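"""Synthetic paired-stage scRNA-seq data with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomially distributed UMI counts, discrete cell clusters
with marker genes, a pair of stage-labeled datasets whose shared sub-types
differ only by a stage-wide multiplicative scalar, planted pseudo-temporal
expression gradients along a cluster chain, and a planted sparse
regulator -> target network.  Toy CEL-Seq2-layout FASTQ files (left read =
6 nt UMI + 6 nt cell barcode + polyT, right read = cDNA) can be emitted with
a truth table for round-trip tests of the quantification stage.

Counts are parameterized as NB(mean m, size r) with variance m + m**2/r, so
every gene is overdispersed relative to Poisson for finite r.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import UMI_SPACE, UmiCountMatrix

_BASES = np.array(list("ACGT"))
POLYT_LENGTH = 12  # fixed polyT tail of toy left reads


@dataclass
class SynthConfig:
    """Parameters of the paired-stage generator.

    ``shared_clusters`` pairs stage-A with stage-B cluster ids; shared
    clusters reuse the same gene-mean vector up to ``stage_effect``.
    ``mean_log_expression_range`` is the log10 range of per-gene baseline
    mean transcripts per cell.  ``trajectory_chain`` names stage-A clusters
    along which ``n_gradient_genes`` genes vary log-linearly with planted
    pseudotime.  ``planted_edges`` lists (regulator, target, coefficient)
    dependencies realized as Poisson draws around a linear function of the
    regulator's counts.
    """

    n_genes: int = 500
    n_cells_per_stage: int = 600
    n_clusters_stage_a: int = 3
    n_clusters_stage_b: int = 3
    shared_clusters: tuple = ((0, 0), (1, 1))
    nb_dispersion: float = 2.0
    mean_log_expression_range: tuple = (-1.0, 1.3)
    n_marker_genes_per_cluster: int = 20
    marker_fold_change: float = 8.0
    stage_effect: float = 1.5
    trajectory_chain: tuple = ()
    n_gradient_genes: int = 0
    gradient_log2_amplitude: float = 3.0
    planted_edges: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_clusters_stage_a < 1 or self.n_clusters_stage_b < 1:
            raise ValueError("need at least one cluster per stage")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        for a, b in self.shared_clusters:
            if not (0 <= a < self.n_clusters_stage_a):
                raise ValueError(f"shared A-cluster {a} out of range")
            if not (0 <= b < self.n_clusters_stage_b):
                raise ValueError(f"shared B-cluster {b} out of range")
        for c in self.trajectory_chain:
            if not (0 <= c < self.n_clusters_stage_a):
                raise ValueError(f"chain cluster {c} out of range")


@dataclass
class GroundTruth:
    """Planted structure of a generated stage pair."""

    labels_a: pd.Series
    labels_b: pd.Series
    correspondence_map: dict
    marker_genes: dict
    de_gene_sets: dict
    pseudotime: pd.Series
    gradient_genes: dict
    planted_edge_list: list
    cluster_means_a: pd.DataFrame
    cluster_means_b: pd.DataFrame


def _split_cells(n_cells: int, n_clusters: int) -> np.ndarray:
    """Cluster label per cell, cells split as evenly as possible."""
    base = n_cells // n_clusters
    sizes = np.full(n_clusters, base)
    sizes[: n_cells - base * n_clusters] += 1
    return np.repeat(np.arange(n_clusters), sizes)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB(mean m, size r): gamma-Poisson mixture, variance m + m^2/r."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        lam = rng.gamma(size_param, mean[pos] / size_param)
        out[pos] = rng.poisson(lam)
    return out


def generate_stage_pair(config: SynthConfig):
    """Generate two stage-labeled UMI count matrices plus ground truth.

    Returns ``(matrix_a, matrix_b, truth)``.  Deterministic given
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"Gene{i:05d}" for i in range(cfg.n_genes)])

    lo, hi = cfg.mean_log_expression_range
    base_means = 10.0 ** rng.uniform(lo, hi, cfg.n_genes)

    # reserve disjoint special gene blocks: markers per cluster + gradients
    n_b_own = cfg.n_clusters_stage_b - len(cfg.shared_clusters)
    n_special = (
        (cfg.n_clusters_stage_a + n_b_own) * cfg.n_marker_genes_per_cluster
        + cfg.n_gradient_genes
    )
    if n_special > cfg.n_genes:
        raise ValueError("not enough genes for markers and gradient genes")
    special = rng.choice(cfg.n_genes, size=n_special, replace=False)
    pos = 0
    marker_idx = {}
    for c in range(cfg.n_clusters_stage_a):
        marker_idx[("A", c)] = special[pos : pos + cfg.n_marker_genes_per_cluster]
        pos += cfg.n_marker_genes_per_cluster
    shared_b = {b: a for a, b in cfg.shared_clusters}
    for c in range(cfg.n_clusters_stage_b):
        if c in shared_b:
            marker_idx[("B", c)] = marker_idx[("A", shared_b[c])]
        else:
            marker_idx[("B", c)] = special[pos : pos + cfg.n_marker_genes_per_cluster]
            pos += cfg.n_marker_genes_per_cluster
    gradient_idx = special[pos : pos + cfg.n_gradient_genes]

    # cluster mean vectors
    means_a = np.tile(base_means, (cfg.n_clusters_stage_a, 1))
    for c in range(cfg.n_clusters_stage_a):
        means_a[c, marker_idx[("A", c)]] *= cfg.marker_fold_change
    means_b = np.tile(base_means, (cfg.n_clusters_stage_b, 1))
    for c in range(cfg.n_clusters_stage_b):
        if c in shared_b:
            means_b[c] = means_a[shared_b[c]] * cfg.stage_effect
        else:
            means_b[c, marker_idx[("B", c)]] *= cfg.marker_fold_change

    labels_a = _split_cells(cfg.n_cells_per_stage, cfg.n_clusters_stage_a)
    labels_b = _split_cells(cfg.n_cells_per_stage, cfg.n_clusters_stage_b)
    cells_a = [f"A_cell{i:04d}" for i in range(cfg.n_cells_per_stage)]
    cells_b = [f"B_cell{i:04d}" for i in range(cfg.n_cells_per_stage)]

    # planted pseudotime along the stage-A chain
    pseudotime = np.full(cfg.n_cells_per_stage, np.nan)
    if cfg.trajectory_chain:
        n_chain = len(cfg.trajectory_chain)
        for pos_i, c in enumerate(cfg.trajectory_chain):
            members = np.flatnonzero(labels_a == c)
            t = (pos_i + np.sort(rng.uniform(0, 1, members.size))) / n_chain
            pseudotime[members] = t
    half = cfg.n_gradient_genes // 2
    early_idx = gradient_idx[:half]
    late_idx = gradient_idx[half:]

    def _cell_means(stage_means, labels, t_vec):
        m = stage_means[labels]  # cells x genes
        if cfg.n_gradient_genes and t_vec is not None:
            on = ~np.isnan(t_vec)
            dev = (t_vec[on] - 0.5) * cfg.gradient_log2_amplitude
            m[np.ix_(on, late_idx)] *= 2.0 ** dev[:, None]
            m[np.ix_(on, early_idx)] *= 2.0 ** (-dev[:, None])
        return m

    cm_a = _cell_means(means_a, labels_a, pseudotime)
    cm_b = _cell_means(means_b, labels_b, None)
    counts_a = _nb_draw(rng, cm_a, cfg.nb_dispersion).T
    counts_b = _nb_draw(rng, cm_b, cfg.nb_dispersion).T

    # planted regulator -> target dependencies (Poisson around linear link)
    gene_pos = {g: i for i, g in enumerate(genes)}
    edge_list = []
    for reg, tgt, coef in cfg.planted_edges:
        ri, ti = gene_pos[reg], gene_pos[tgt]
        for counts in (counts_a, counts_b):
            counts[ti] = rng.poisson(coef * counts[ri] + 0.1)
        edge_list.append((reg, tgt, float(coef)))

    np.clip(counts_a, 0, UMI_SPACE - 1, out=counts_a)
    np.clip(counts_b, 0, UMI_SPACE - 1, out=counts_b)

    def _pack(counts, cells, labels, stage):
        df = pd.DataFrame(counts, index=genes, columns=cells)
        meta = pd.DataFrame(
            {"stage": stage, "cluster_truth": labels, "plate": 0}, index=cells
        )
        return UmiCountMatrix(counts=df, cell_meta=meta)

    mat_a = _pack(counts_a, cells_a, labels_a, "A")
    mat_b = _pack(counts_b, cells_b, labels_b, "B")

    marker_genes = {k: list(genes[v]) for k, v in marker_idx.items()}
    de_gene_sets = {}
    for stage, n_c in (("A", cfg.n_clusters_stage_a), ("B", cfg.n_clusters_stage_b)):
        for i in range(n_c):
            for j in range(i + 1, n_c):
                de_gene_sets[(stage, i, j)] = frozenset(
                    set(marker_genes[(stage, i)]) ^ set(marker_genes[(stage, j)])
                )
    truth = GroundTruth(
        labels_a=pd.Series(labels_a, index=cells_a, name="cluster"),
        labels_b=pd.Series(labels_b, index=cells_b, name="cluster"),
        correspondence_map=dict(cfg.shared_clusters),
        marker_genes=marker_genes,
        de_gene_sets=de_gene_sets,
        pseudotime=pd.Series(pseudotime, index=cells_a, name="pseudotime"),
        gradient_genes={
            "early": list(genes[early_idx]),
            "late": list(genes[late_idx]),
        },
        planted_edge_list=edge_list,
        cluster_means_a=pd.DataFrame(means_a.T, index=genes),
        cluster_means_b=pd.DataFrame(means_b.T, index=genes),
    )
    return mat_a, mat_b, truth


# ---------------------------------------------------------------------------
# toy FASTQ generation


def _random_seq(rng, length):
    return "".join(rng.choice(_BASES, size=length))


def generate_toy_fastq(
    config: SynthConfig,
    reads_per_cell: int,
    out_dir,
    n_loci: int = 20,
    locus_length: int = 300,
    read_length: int = 50,
    multimap_fraction: float = 0.0,
    off_whitelist_fraction: float = 0.0,
    duplicate_fraction: float = 0.0,
    gzip_output: bool = False,
):
    """Emit paired toy FASTQ files in CEL-Seq2 layout plus a truth table.

    Left reads are 6 nt UMI + 6 nt cell barcode + a fixed 12 nt polyT tail;
    right reads are exact sense substrings of synthetic gene-locus sequences.
    ``multimap_fraction`` of reads originate from a sequence block shared by
    two loci (expected assignment MULTI); ``off_whitelist_fraction`` carry a
    barcode absent from the plate whitelist; ``duplicate_fraction`` re-emits
    an existing (cell, gene, UMI) molecule and must collapse to one UMI.

    Returns ``(left_path, right_path, truth, whitelist, locus_seqs)`` where
    ``truth`` is a DataFrame with columns read_id, barcode, umi, locus (locus
    is ``MULTI`` for planted multimappers) and ``expected_barcode_ok``.
    """
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be > 0")
    rng = np.random.default_rng(config.seed + 7)
    n_cells = min(config.n_cells_per_stage, 96)
    if n_cells < 1:
        raise ValueError("need at least one cell")

    barcodes = set()
    while len(barcodes) < n_cells + 8:  # extras serve as off-whitelist codes
        barcodes.add(_random_seq(rng, 6))
    barcodes = sorted(barcodes)
    whitelist = barcodes[:n_cells]
    off_codes = barcodes[n_cells:]

    locus_ids = [f"Locus{i:03d}" for i in range(n_loci)]
    locus_seqs = {lid: _random_seq(rng, locus_length) for lid in locus_ids}
    shared_block = _random_seq(rng, read_length + 10)
    if multimap_fraction > 0 and n_loci >= 2:
        # plant an identical block in the first two loci
        for lid in locus_ids[:2]:
            locus_seqs[lid] = locus_seqs[lid][: locus_length - len(shared_block)] + shared_block

    rows = []
    left_records, right_records = [], []
    molecules = []  # (barcode, umi, locus, right_seq) for duplication
    rid = 0
    for bc in whitelist:
        for _ in range(reads_per_cell):
            u = rng.uniform()
            umi = _random_seq(rng, 6)
            barcode, bc_ok = bc, True
            if duplicate_fraction > 0 and molecules and u < duplicate_fraction:
                barcode, umi, locus, right = molecules[
                    rng.integers(len(molecules))
                ]
                bc_ok = barcode in whitelist
            elif multimap_fraction > 0 and u < duplicate_fraction + multimap_fraction:
                locus = "MULTI"
                start = rng.integers(0, len(shared_block) - read_length + 1)
                right = shared_block[start : start + read_length]
            else:
                if (
                    off_whitelist_fraction > 0
                    and u < duplicate_fraction + multimap_fraction + off_whitelist_fraction
                ):
                    barcode, bc_ok = off_codes[rng.integers(len(off_codes))], False
                locus = locus_ids[rng.integers(n_loci)]
                seq = locus_seqs[locus]
                hi = len(seq) - read_length + 1
                if multimap_fraction > 0 and locus in locus_ids[:2]:
                    # keep ordinary reads clear of the planted shared block so
                    # only planted multimappers are ambiguous
                    hi = min(hi, len(seq) - len(shared_block) - read_length + 1)
                start = rng.integers(0, hi)
                right = seq[start : start + read_length]
                if locus != "MULTI" and bc_ok:
                    molecules.append((barcode, umi, locus, right))
            read_id = f"read{rid:07d}"
            rid += 1
            left = umi + barcode + "T" * POLYT_LENGTH
            left_records.append((read_id, left))
            right_records.append((read_id, right))
            rows.append((read_id, barcode, umi, locus, bc_ok))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    left_path = out_dir / f"reads_R1{suffix}"
    right_path = out_dir / f"reads_R2{suffix}"
    for path, records in ((left_path, left_records), (right_path, right_records)):
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as fh:
            for read_id, seq in records:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    truth = pd.DataFrame(
        rows, columns=["read_id", "barcode", "umi", "locus", "expected_barcode_ok"]
    )
    return left_path, right_path, truth, whitelist, locus_seqs


def truth_umi_counts(truth: pd.DataFrame, whitelist) -> pd.DataFrame:
    """Expected genes x cells distinct-UMI matrix implied by a truth table."""
    ok = truth[
        truth["expected_barcode_ok"]
        & (truth["locus"] != "MULTI")
        & (truth["locus"] != "UNMAPPED")
    ]
    dedup = ok.drop_duplicates(["barcode", "umi", "locus"])
    mat = (
        dedup.groupby(["locus", "barcode"]).size().unstack(fill_value=0)
    )
    return mat.reindex(columns=list(whitelist), fill_value=0)


def config_to_dict(config: SynthConfig) -> dict:
    return dataclasses.asdict(config)
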