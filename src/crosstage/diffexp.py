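"""Negative-binomial exact test for differential expression between groups.

Per gene, the normalized counts of each cell group are summed and rounded,
and the two group sums (kA, kB) are compared under an exact conditional test
in the spirit of the NB exact test of count-based DE analysis: with P_A and
P_B the NB mass functions of the two group sums, the p-value is the
probability, conditional on the observed total kA + kB, of all splits (a, b)
no more likely than the observed one:

    p = sum_{a+b=T, P_A(a) P_B(b) <= P_A(kA) P_B(kB)} P_A(a) P_B(b)
        / sum_{a+b=T} P_A(a) P_B(b)

The NB variance of each group comes from the background noise model
evaluated at the per-cell group mean, scaled to the n-cell sum by matched
moments (mean n*m, variance n*v(m)).  Benjamini-Hochberg correction is
applied across genes.  For large totals the conditional distribution is
replaced by a normal approximation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .cluster import BackgroundNoiseModel
from .containers import TranscriptCountMatrix

#: totals above this use the normal approximation to the conditional law
EXHAUSTIVE_LIMIT = 5000


def _group_nb_params(mean_cell: float, n_cells: int, noise: BackgroundNoiseModel):
    """(size r, success prob p, mean, variance) of an n-cell NB group sum."""
    mean_cell = max(float(mean_cell), 1e-12)
    m = n_cells * mean_cell
    v = n_cells * float(noise.predict_variance(mean_cell))
    v = max(v, m * (1 + 1e-9))
    r = m * m / (v - m)
    p = r / (r + m)
    return r, p, m, v


def nb_exact_test(
    kA: int,
    kB: int,
    meanA: float,
    meanB: float,
    noise: BackgroundNoiseModel,
    nA: int = 1,
    nB: int = 1,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> float:
    """Exact conditional NB p-value for two observed group sums.

    ``meanA``/``meanB`` are per-cell means under the null (typically the
    pooled mean), ``nA``/``nB`` the group sizes.  Symmetric under swapping
    the groups; returns 1.0 for a zero total.
    """
    if kA < 0 or kB < 0:
        raise ValueError("group counts must be non-negative")
    if float(kA) != int(kA) or float(kB) != int(kB):
        warnings.warn("non-integer group counts rounded for the exact test")
    kA, kB = int(round(kA)), int(round(kB))
    T = kA + kB
    if T == 0:
        return 1.0
    rA, pA, mA, vA = _group_nb_params(meanA, nA, noise)
    rB, pB, mB, vB = _group_nb_params(meanB, nB, noise)
    if T <= exhaustive_limit:
        a = np.arange(T + 1)
        lj = stats.nbinom.logpmf(a, rA, pA) + stats.nbinom.logpmf(T - a, rB, pB)
        denom = logsumexp(lj)
        obs = lj[kA]
        num = logsumexp(lj[lj <= obs + 1e-12])
        return float(min(np.exp(num - denom), 1.0))
    # normal approximation to the conditional distribution of a | a+b=T
    mu = mA + (T - mA - mB) * vA / (vA + vB)
    sd = np.sqrt(vA * vB / (vA + vB))
    z = (abs(kA - mu) - 0.5) / sd
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diffexpnb(
    matrix,
    cells_A,
    cells_B,
    noise: BackgroundNoiseModel,
    pseudocount: float = 0.1,
    genes=None,
) -> pd.DataFrame:
    """Per-gene NB exact test between two disjoint cell groups.

    ``matrix`` is a genes x cells DataFrame of normalized counts or a
    :class:`TranscriptCountMatrix`.  Returns a DataFrame indexed by gene with
    columns meanA, meanB, log2_fold_change, pval, padj.
    """
    counts = matrix.counts if isinstance(matrix, TranscriptCountMatrix) else matrix
    cells_A, cells_B = list(cells_A), list(cells_B)
    if not cells_A or not cells_B:
        raise ValueError("both cell groups must be non-empty")
    if set(cells_A) & set(cells_B):
        raise ValueError("cell groups overlap")
    sub = counts.loc[genes] if genes is not None else counts
    A = sub[cells_A].values
    B = sub[cells_B].values
    sumA, sumB = A.sum(axis=1), B.sum(axis=1)
    if not (
        np.allclose(sumA, np.round(sumA), atol=1e-9)
        and np.allclose(sumB, np.round(sumB), atol=1e-9)
    ):
        warnings.warn("non-integer group sums rounded for the exact test")
    nA, nB = len(cells_A), len(cells_B)
    meanA, meanB = sumA / nA, sumB / nB
    pooled = (sumA + sumB) / (nA + nB)
    pvals = np.ones(sub.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rounding warned once above
        for i in range(sub.shape[0]):
            pvals[i] = nb_exact_test(
                int(round(sumA[i])),
                int(round(sumB[i])),
                pooled[i],
                pooled[i],
                noise,
                nA=nA,
                nB=nB,
            )
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "meanA": meanA,
            "meanB": meanB,
            "log2_fold_change": np.log2((meanB + pseudocount) / (meanA + pseudocount)),
            "pval": pvals,
            "padj": padj,
        },
        index=sub.index,
    )


def significant_genes(de_table: pd.DataFrame, padj_threshold: float = 0.05):
    """Genes shortlisted at a BH-adjusted p-value threshold (default 0.05)."""
    return list(de_table.index[de_table["padj"] < padj_threshold])
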