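"""Cognitive-battery cleaning and PCA extraction of the general-cognition factor.

Rows missing more than ``max_missing`` test scores are excluded; remaining
missing cells get the column mean.  PCA is run on the correlation scale
(columns standardized) and the first component, sign-oriented against an
anchor test, is the per-subject general-cognition score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["PCAModel", "GScores", "impute_cognitive", "fit_pca", "extract_g"]


@dataclasses.dataclass
class PCAModel:
    component_loadings: np.ndarray  # p x K, unit-norm columns
    explained_variance: np.ndarray  # K proportions, nonincreasing
    contributions: np.ndarray  # p x K percentages, each column sums to 100
    center: np.ndarray  # p column means
    scale: np.ndarray  # p column SDs (ddof=1)
    test_names: list[str]


@dataclasses.dataclass
class GScores:
    g: pd.Series  # standardized, indexed by subject_id
    excluded_ids: list


def _split(matrix: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    if "subject_id" in matrix.columns:
        return matrix["subject_id"], matrix.drop(columns="subject_id")
    return pd.Series(matrix.index), matrix


def impute_cognitive(matrix: pd.DataFrame, max_missing: int = 5) -> tuple[pd.DataFrame, list]:
    """Exclude rows with more than ``max_missing`` missing tests, then mean-impute.

    Column means are computed on the post-exclusion sample, over observed
    values only.  Returns the imputed table and the excluded subject ids.
    """
    ids, values = _split(matrix)
    n_tests = values.shape[1]
    if max_missing >= n_tests:
        raise ValueError(f"max_missing ({max_missing}) must be < number of tests ({n_tests})")
    n_missing = values.isna().sum(axis=1)
    keep = n_missing <= max_missing
    excluded = list(ids[~keep])
    kept = values.loc[keep]
    all_missing = kept.columns[kept.isna().all(axis=0)] if len(kept) else kept.columns
    if len(kept) and len(all_missing):
        raise ValueError(f"column(s) entirely missing, no mean defined: {list(all_missing)}")
    filled = kept.fillna(kept.mean(axis=0))
    out = filled.copy()
    out.insert(0, "subject_id", list(ids[keep]))
    return out.reset_index(drop=True), excluded


def fit_pca(matrix: pd.DataFrame) -> PCAModel:
    """PCA of the standardized test matrix (correlation-scale decomposition)."""
    _, values = _split(matrix)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than tests ({p})")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        names = [values.columns[j] for j in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    Xs = (X - center) / scale
    _, svals, vt = np.linalg.svd(Xs, full_matrices=False)
    eigvals = svals**2 / (n - 1)  # eigenvalues of the sample correlation matrix
    explained = eigvals / eigvals.sum()
    loadings = vt.T  # p x K, unit-norm columns
    contributions = 100.0 * loadings**2
    return PCAModel(
        component_loadings=loadings,
        explained_variance=explained,
        contributions=contributions,
        center=center,
        scale=scale,
        test_names=list(values.columns),
    )


def extract_g(model: PCAModel, matrix: pd.DataFrame, anchor_test: str = "WRAT") -> GScores:
    """Score subjects on PC1, oriented so the anchor test correlates positively."""
    if anchor_test not in model.test_names:
        raise ValueError(f"anchor test {anchor_test!r} not among {model.test_names}")
    ids, values = _split(matrix)
    X = values[model.test_names].to_numpy(dtype=float)
    Xs = (X - model.center) / model.scale
    scores = Xs @ model.component_loadings[:, 0]
    anchor = X[:, model.test_names.index(anchor_test)]
    r = np.corrcoef(scores, anchor)[0, 1]
    if not np.isfinite(r) or r == 0:
        raise ValueError("orientation undefined: g uncorrelated with the anchor test")
    if r < 0:
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return GScores(g=pd.Series(scores, index=pd.Index(ids, name="subject_id"), name="g"), excluded_ids=[])
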