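"""UMI quantification for CEL-Seq2-layout paired reads.

The left read carries the molecular information: the first six bases are the
unique molecular identifier (UMI), the next six the cell barcode, and the
remainder a polyT stretch.  The right read is cDNA and is assigned to a gene
locus in sense direction only; reads matching more than one locus are
discarded as MULTI.  Per (gene locus, cell) the number of distinct UMIs k is
counted, and k is converted to a transcript count with the binomial collision
correction for a K-state UMI space (K = 4096 for 6 nt UMIs):

    t(k) = ln(1 - k'/K) / ln(1 - 1/K),   k' = min(k, K - 1)

which is the expected number of molecules that would produce k distinct UMIs
when each molecule draws a UMI uniformly at random.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import UMI_SPACE, UmiCountMatrix

UMI_LENGTH = 6
BARCODE_LENGTH = 6
MULTI = "MULTI"
UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class ReadAssignment:
    """One read pair resolved to (cell barcode, UMI, gene locus)."""

    read_id: str
    barcode: str
    umi: str
    locus: str


@dataclass(frozen=True)
class GeneLocus:
    """A gene locus as a 0-based half-open genomic interval."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative coordinate in locus {self.id}")
        if self.start >= self.end:
            raise ValueError(f"locus {self.id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


class ExactMatchAssigner:
    """Assign a cDNA read to gene loci by exact sense-strand substring match.

    A stand-in for a genomic aligner with the same output contract: a read
    maps to every locus whose sense sequence contains it; antisense matches
    are not considered, so a read present only in reverse complement is
    UNMAPPED.
    """

    def __init__(self, locus_seqs: dict):
        self.locus_seqs = dict(locus_seqs)

    def __call__(self, seq: str) -> list:
        return [lid for lid, ref in self.locus_seqs.items() if seq in ref]


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_read_pairs(
    fastq_left,
    fastq_right,
    barcode_whitelist,
    locus_assigner,
    min_polyt: int = 4,
):
    """Resolve paired FASTQ reads into :class:`ReadAssignment` records.

    Returns ``(assignments, report)`` where ``report`` counts excluded reads
    by reason (off_whitelist, ambiguous_base, short_left, no_polyt) and the
    assignment outcome of retained reads.  Reads with barcodes absent from
    the whitelist, or with N in UMI/barcode, are excluded up front.
    """
    whitelist = set(barcode_whitelist)
    if not whitelist:
        raise ValueError("barcode whitelist must be non-empty")
    report = {
        "total": 0,
        "off_whitelist": 0,
        "ambiguous_base": 0,
        "short_left": 0,
        "no_polyt": 0,
        "assigned": 0,
        "multi": 0,
        "unmapped": 0,
    }
    assignments = []
    with _open_maybe_gzip(fastq_left) as fl, _open_maybe_gzip(fastq_right) as fr:
        left_iter = SeqIO.parse(fl, "fastq")
        right_iter = SeqIO.parse(fr, "fastq")
        idx = -1
        while True:
            idx += 1
            try:
                left = next(left_iter, None)
                right = next(right_iter, None)
            except ValueError as exc:  # malformed FASTQ record
                raise ValueError(f"malformed FASTQ at record {idx}: {exc}") from exc
            if left is None and right is None:
                break
            if left is None or right is None:
                raise ValueError(
                    f"malformed FASTQ: files differ in length at record {idx}"
                )
            report["total"] += 1
            lseq = str(left.seq).upper()
            if len(lseq) < UMI_LENGTH + BARCODE_LENGTH + min_polyt:
                report["short_left"] += 1
                continue
            umi = lseq[:UMI_LENGTH]
            barcode = lseq[UMI_LENGTH : UMI_LENGTH + BARCODE_LENGTH]
            tail = lseq[UMI_LENGTH + BARCODE_LENGTH :]
            if set(umi + barcode) - set("ACGT"):
                report["ambiguous_base"] += 1
                continue
            if not tail.startswith("T" * min_polyt):
                report["no_polyt"] += 1
                continue
            if barcode not in whitelist:
                report["off_whitelist"] += 1
                continue
            hits = locus_assigner(str(right.seq).upper())
            if len(hits) == 0:
                locus = UNMAPPED
                report["unmapped"] += 1
            elif len(hits) > 1:
                locus = MULTI
                report["multi"] += 1
            else:
                locus = hits[0]
                report["assigned"] += 1
            assignments.append(
                ReadAssignment(read_id=left.id, barcode=barcode, umi=umi, locus=locus)
            )
    return assignments, report


def read_assignment_table(path) -> list:
    """Load a precomputed read -> locus table (TSV: read_id, barcode, umi, locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"read_id", "barcode", "umi", "locus"}
    if not required.issubset(df.columns):
        raise ValueError(f"assignment table must have columns {sorted(required)}")
    return [
        ReadAssignment(r.read_id, r.barcode, r.umi, r.locus)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# gene-locus merging


def merge_gene_loci(loci, overlap_fraction: float = 0.75):
    """Merge gene loci whose overlap strictly exceeds a fraction of the shorter.

    Merging is transitive (union-find closure) and restricted to loci on the
    same chromosome and strand; the merged interval is the union of member
    intervals and the merged id joins member ids with ``|``.

    Returns ``(merged_loci, id_map)`` with ``id_map`` mapping every input id
    to its merged id.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    loci = sorted(loci, key=lambda l: (l.chromosome, l.strand, l.start, l.end, l.id))
    parent = list(range(len(loci)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, a in enumerate(loci):
        for j in range(i + 1, len(loci)):
            b = loci[j]
            if (b.chromosome, b.strand) != (a.chromosome, a.strand):
                break
            overlap = min(a.end, b.end) - max(a.start, b.start)
            if overlap <= 0:
                continue
            shorter = min(a.length, b.length)
            if overlap > overlap_fraction * shorter:
                union(i, j)

    groups = {}
    for i in range(len(loci)):
        groups.setdefault(find(i), []).append(i)
    merged, id_map = [], {}
    for members in groups.values():
        ids = sorted(loci[i].id for i in members)
        new_id = "|".join(ids)
        first = loci[members[0]]
        merged.append(
            GeneLocus(
                id=new_id,
                chromosome=first.chromosome,
                start=min(loci[i].start for i in members),
                end=max(loci[i].end for i in members),
                strand=first.strand,
            )
        )
        for i in members:
            id_map[loci[i].id] = new_id
    merged.sort(key=lambda l: (l.chromosome, l.start))
    return merged, id_map


def read_bed_loci(path) -> list:
    """Read loci from a BED file (chrom, start, end, name, score, strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(GeneLocus(name, chrom, start, end, strand))
    return out


# ---------------------------------------------------------------------------
# UMI counting and collision correction


def count_umis(assignments, id_map=None, cell_meta=None) -> UmiCountMatrix:
    """Count distinct UMIs per (gene locus, cell barcode).

    MULTI and UNMAPPED assignments are skipped; ``id_map`` (from
    :func:`merge_gene_loci`) aggregates transcripts of the same gene group.
    ERCC spike-in loci (ids starting with ``ERCC-``) are counted but tagged
    separately on the returned matrix.
    """
    triples = set()
    for a in assignments:
        if a.locus in (MULTI, UNMAPPED):
            continue
        locus = id_map.get(a.locus, a.locus) if id_map else a.locus
        triples.add((locus, a.barcode, a.umi))
    if not triples:
        counts = pd.DataFrame(dtype=np.int64)
    else:
        df = pd.DataFrame(list(triples), columns=["locus", "barcode", "umi"])
        counts = (
            df.groupby(["locus", "barcode"]).size().unstack(fill_value=0).astype(np.int64)
        )
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    spikes = tuple(g for g in counts.index if str(g).startswith("ERCC-"))
    return UmiCountMatrix(counts=counts, cell_meta=cell_meta, spike_genes=spikes)


def umi_to_transcripts(k, K: int = UMI_SPACE):
    """Binomial collision correction: observed distinct UMIs -> transcripts.

    ``t = ln(1 - k'/K) / ln(1 - 1/K)`` with ``k' = min(k, K - 1)``; the clamp
    avoids the singularity at full UMI saturation.  Monotone non-decreasing
    in k, with t(0) = 0 and t(1) = 1 exactly.
    """
    arr = np.asarray(k, dtype=float)
    if (arr < 0).any():
        raise ValueError("UMI counts must be non-negative")
    if (arr > K).any():
        raise ValueError(f"UMI count exceeds UMI space size K={K}")
    clamped = np.minimum(arr, K - 1)
    t = np.log1p(-clamped / K) / np.log1p(-1.0 / K)
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(t)
    return t


def correct_matrix(matrix: UmiCountMatrix) -> pd.DataFrame:
    """Apply the collision correction entrywise to a UMI count matrix."""
    vals = umi_to_transcripts(matrix.counts.values, matrix.umi_space)
    return pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)


def quantify_fastq(
    fastq_left,
    fastq_right,
    barcode_whitelist,
    locus_assigner,
    id_map=None,
):
    """End-to-end: paired FASTQ -> collision-corrected transcript matrix.

    Returns ``(umi_matrix, corrected, report)``.
    """
    assignments, report = parse_read_pairs(
        fastq_left, fastq_right, barcode_whitelist, locus_assigner
    )
    umi_matrix = count_umis(assignments, id_map=id_map)
    return umi_matrix, correct_matrix(umi_matrix), report
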