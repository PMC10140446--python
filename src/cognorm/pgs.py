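"""Polygenic scores over a p-value-threshold grid, collapsed to one component.

For each threshold t, a subject's score is the dosage-weighted sum of the
effect sizes of all SNPs with GWAS p-value <= t.  Rather than choosing one
threshold, the full subjects-by-thresholds score matrix is decomposed by
PCA and its first component carried forward.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["PRSMatrix", "PGSComponent", "default_thresholds", "compute_prs_matrix", "prs_pca"]

N_DEFAULT_THRESHOLDS = 6002
GENOME_WIDE = 5e-8


@dataclasses.dataclass
class PRSMatrix:
    scores: np.ndarray  # n x T
    thresholds: np.ndarray  # T ascending values in [5e-8, 0.5]
    subject_ids: list


@dataclasses.dataclass
class PGSComponent:
    score: np.ndarray  # n values, first PC of the (standardized) PRS matrix
    explained_variance: float
    subject_ids: list


def default_thresholds(
    n: int = N_DEFAULT_THRESHOLDS, low: float = GENOME_WIDE, high: float = 0.5
) -> np.ndarray:
    """Uniform grid of ``n`` thresholds from the genome-wide level up to ``high``."""
    if n < 1:
        raise ValueError("need at least one threshold")
    return np.linspace(low, high, n)


def compute_prs_matrix(
    dosages: pd.DataFrame, stats: pd.DataFrame, thresholds: np.ndarray | None = None
) -> PRSMatrix:
    """Per-subject polygenic scores at every p-value threshold.

    ``dosages``: subject rows, SNP dosage columns (plus optional
    ``subject_id``); every SNP column must appear in ``stats``
    (columns ``snp_id``, ``beta``, ``p_value``).
    """
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")

    if "subject_id" in dosages.columns:
        subject_ids = list(dosages["subject_id"])
        dos = dosages.drop(columns="subject_id")
    else:
        subject_ids = list(dosages.index)
        dos = dosages

    if stats["snp_id"].duplicated().any():
        dups = stats.loc[stats["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_ids in summary stats: {dups[:5]}")
    lookup = stats.set_index("snp_id")
    missing = [c for c in dos.columns if c not in lookup.index]
    if missing:
        raise ValueError(f"SNP(s) in dosages without summary stats: {missing[:10]}")

    beta = lookup.loc[dos.columns, "beta"].to_numpy(dtype=float)
    pval = lookup.loc[dos.columns, "p_value"].to_numpy(dtype=float)
    if np.any(pval <= 0) or np.any(pval > 1):
        raise ValueError("p_values must lie in (0, 1]")

    X = dos.to_numpy(dtype=float)
    order = np.argsort(pval, kind="stable")
    weighted = X[:, order] * beta[order][None, :]
    cumulative = np.cumsum(weighted, axis=1)
    # number of SNPs admitted at each threshold
    counts = np.searchsorted(pval[order], thresholds, side="right")
    scores = np.zeros((X.shape[0], thresholds.size))
    nonzero = counts > 0
    scores[:, nonzero] = cumulative[:, counts[nonzero] - 1]
    return PRSMatrix(scores=scores, thresholds=thresholds, subject_ids=subject_ids)


def prs_pca(matrix: PRSMatrix) -> PGSComponent:
    """First principal component of the centered-and-scaled threshold-score matrix.

    Constant columns (thresholds admitting no SNP) carry no information and
    are dropped before standardization.
    """
    X = np.asarray(matrix.scores, dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-constant threshold columns for PCA")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    _, svals, vt = np.linalg.svd(Xs, full_matrices=False)
    eigvals = svals**2
    score = Xs @ vt[0]
    # orient positively against the densest (last) threshold column
    r = np.corrcoef(score, Xs[:, -1])[0, 1]
    if np.isfinite(r) and r < 0:
        score = -score
    return PGSComponent(
        score=score,
        explained_variance=float(eigvals[0] / eigvals.sum()),
        subject_ids=matrix.subject_ids,
    )
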