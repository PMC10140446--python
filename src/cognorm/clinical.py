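"""Clinical-item imputation and ICA decomposition into symptom components.

Missing ordinal items are filled from the nearest neighbouring subject
(Euclidean distance over jointly observed, standardized items, scaled by
the number of shared items).  The completed matrix is decomposed into k
independent components via restarted FastICA with Icasso-style cluster
aggregation: runs are clustered by absolute loading correlation and each
cluster's centrotype is kept, with a cluster-compactness stability index.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA

__all__ = [
    "ICAModel",
    "ClinicalComponents",
    "knn_impute",
    "fit_ica",
    "general_psychopathology",
    "amari_index",
]


@dataclasses.dataclass
class ICAModel:
    mixing: np.ndarray  # items x k
    unmixing: np.ndarray  # k x items
    component_scores: np.ndarray  # n x k, standardized
    stability_index: np.ndarray  # k values in [0, 1]
    restarts: int
    item_names: list[str]


@dataclasses.dataclass
class ClinicalComponents:
    scores: pd.DataFrame  # subject_id + IC1..ICk, standardized
    general: pd.Series  # row mean of the k component scores

    @property
    def component_names(self) -> list[str]:
        return [c for c in self.scores.columns if c.startswith("IC")]


def _split(matrix: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    if "subject_id" in matrix.columns:
        return matrix["subject_id"], matrix.drop(columns="subject_id")
    return pd.Series(matrix.index), matrix


def knn_impute(items: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Fill each missing cell from the nearest donor subject.

    Distance between a recipient and a donor is the mean squared difference
    of standardized values over their jointly observed items (so rows with
    different missingness patterns are comparable); ties break toward the
    lowest subject index.  Donors are visited in distance order until every
    missing cell is filled.  Rows with no observed items are excluded.
    """
    ids, values = _split(items)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    all_missing = ~obs.any(axis=1)
    excluded = list(ids[all_missing])
    keep = ~all_missing
    X = X[keep]
    obs = obs[keep]
    kept_ids = list(ids[keep])
    n = X.shape[0]
    if n == 0:
        raise ValueError("no rows with observed items")
    if not obs.all(axis=1).any():
        raise ValueError("need at least one complete row to donate values")

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Zf = np.where(obs, Z, 0.0)
    O = obs.astype(float)
    sq = Zf**2

    filled = X.copy()
    recipients = np.flatnonzero(~obs.all(axis=1))
    for i in recipients:
        # scaled squared distance to every donor over jointly observed items
        shared = O[i] @ O.T
        d2 = sq[i] @ O.T + O[i] @ sq.T - 2.0 * Zf[i] @ Zf.T
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(shared > 0, d2 / shared, np.inf)
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")
        need = np.flatnonzero(~obs[i])
        for j in order:
            if not np.isfinite(dist[j]) or need.size == 0:
                break
            give = need[obs[j, need]]
            filled[i, give] = X[j, give]
            need = need[~obs[j, need]]
        if need.size:
            raise ValueError(f"row {kept_ids[i]!r}: no donor observes item(s) {need.tolist()}")

    out = pd.DataFrame(filled, columns=values.columns)
    out.insert(0, "subject_id", kept_ids)
    return out.reset_index(drop=True), excluded


def _orient_components(
    scores: np.ndarray, mixing: np.ndarray, unmixing: np.ndarray, X_std: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip signs so each component correlates positively with its loaded-item sum."""
    k = mixing.shape[1]
    for j in range(k):
        col = mixing[:, j]
        top = np.abs(col) >= 0.5 * np.abs(col).max()
        item_sum = X_std[:, top].sum(axis=1)
        r = np.corrcoef(scores[:, j], item_sum)[0, 1]
        if not np.isfinite(r) or r == 0:
            raise ValueError(f"component {j + 1}: orientation undefined (zero correlation)")
        if r < 0:
            scores[:, j] *= -1
            mixing[:, j] *= -1
            unmixing[j, :] *= -1
    return scores, mixing, unmixing


def fit_ica(
    items: pd.DataFrame,
    k: int = 7,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> ICAModel:
    """Restarted FastICA with cluster-centrotype aggregation.

    All ``n_restarts`` runs contribute k loading vectors each; the pooled
    vectors are average-linkage clustered on (1 - |corr|) into k clusters.
    Each cluster's centrotype (member with the highest mean absolute
    correlation to its cluster) is returned, with stability = mean within-
    cluster |corr| minus mean |corr| to outside members, clipped to [0, 1].
    """
    ids, values = _split(items)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("items contain missing values; impute first")
    if n <= 10 * k:
        raise ValueError(f"need n > {10 * k} subjects for k={k} components, got {n}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [values.columns[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant item(s): {bad}")
    X_std = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_restarts):
        ica = FastICA(
            n_components=k,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        sources = ica.fit_transform(X_std)
        runs.append({"mixing": ica.mixing_.copy(), "unmixing": ica.components_.copy(), "sources": sources})

    # pool loading vectors across runs and cluster by absolute correlation
    loadings = np.concatenate([r["mixing"].T for r in runs], axis=0)  # (k*R) x p
    norm = loadings / np.linalg.norm(loadings, axis=1, keepdims=True)
    sim = np.abs(norm @ norm.T)  # |cosine| between loading vectors
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"), t=k, criterion="maxclust")
    cluster_ids = np.unique(labels)
    min_size = 2 if n_restarts >= 2 else 1
    stable = [c for c in cluster_ids if np.sum(labels == c) >= min_size]
    if len(stable) < k:
        raise ValueError(
            f"only {len(stable)} stable component clusters found (need {k}); "
            "increase n_restarts or lower k"
        )

    mixing = np.empty((p, k))
    unmixing = np.empty((k, p))
    scores = np.empty((n, k))
    stability = np.empty(k)
    for out_j, c in enumerate(cluster_ids[:k]):
        members = np.flatnonzero(labels == c)
        within = sim[np.ix_(members, members)]
        centro = members[np.argmax(within.mean(axis=1))]
        outside = np.flatnonzero(labels != c)
        intra = (within.sum(axis=1) - 1.0) / max(len(members) - 1, 1)
        extra = sim[np.ix_(members, outside)].mean(axis=1) if outside.size else np.zeros(len(members))
        stability[out_j] = np.clip(np.mean(intra - extra), 0.0, 1.0)
        run_idx, comp_idx = divmod(centro, k)
        mixing[:, out_j] = runs[run_idx]["mixing"][:, comp_idx]
        unmixing[out_j, :] = runs[run_idx]["unmixing"][comp_idx, :]
        scores[:, out_j] = runs[run_idx]["sources"][:, comp_idx]

    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    scores, mixing, unmixing = _orient_components(scores, mixing, unmixing, X_std)
    return ICAModel(
        mixing=mixing,
        unmixing=unmixing,
        component_scores=scores,
        stability_index=stability,
        restarts=n_restarts,
        item_names=list(values.columns),
    )


def component_table(model: ICAModel, subject_ids) -> ClinicalComponents:
    """Standardized component scores labelled IC1..ICk plus the mean-score proxy."""
    k = model.component_scores.shape[1]
    scores = pd.DataFrame(model.component_scores, columns=[f"IC{j + 1}" for j in range(k)])
    scores.insert(0, "subject_id", list(subject_ids))
    general = general_psychopathology(scores)
    return ClinicalComponents(scores=scores, general=general)


def general_psychopathology(components: pd.DataFrame | ClinicalComponents) -> pd.Series:
    """Arithmetic row mean of the component scores — the general-psychopathology proxy."""
    if isinstance(components, ClinicalComponents):
        frame = components.scores
    else:
        frame = components
    ic_cols = [c for c in frame.columns if c.startswith("IC")]
    if not ic_cols:
        raise ValueError("no component score columns (IC*) present")
    general = frame[ic_cols].mean(axis=1)
    general.name = "general"
    return general


def amari_index(unmixing_est: np.ndarray, mixing_true: np.ndarray) -> float:
    """Permutation- and scale-invariant recovery error; 0 = perfect unmixing."""
    P = np.abs(np.asarray(unmixing_est) @ np.asarray(mixing_true))
    k = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * k * (k - 1)))
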