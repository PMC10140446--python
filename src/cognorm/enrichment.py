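"""Decile binning of deviation scores and clinical-risk enrichment tables.

Subjects are sorted by deviation z-score (best performance first) into ten
equal-frequency bins; remainder subjects go to the first bins, so 6481
subjects give one bin of 649 and nine of 648.  Within each bin the count
and proportion of subjects above symptom thresholds (1/1.5/2/3 SD over
the full-cohort mean) are tabulated, and a worst-vs-best-bin odds ratio
is formed from the 2x2 cross table.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

__all__ = [
    "DecileAssignment",
    "assign_deciles",
    "risk_proportions",
    "odds_ratio",
    "enrichment_tables",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1.0, 1.5, 2.0, 3.0)


@dataclasses.dataclass
class DecileAssignment:
    bin: np.ndarray  # per-subject integer 1..n_bins; 1 = best performance
    boundaries: np.ndarray  # n_bins - 1 z-values separating consecutive bins

    @property
    def n_bins(self) -> int:
        return int(self.bin.max()) if self.bin.size else 0


def assign_deciles(z: np.ndarray, n_bins: int = 10) -> DecileAssignment:
    """Equal-frequency bins of z, bin 1 = highest z (best performance).

    With n = q*n_bins + r, the first r bins receive one extra subject.
    Ties break by stable input order.
    """
    z = np.asarray(z, dtype=float).ravel()
    n = z.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} subjects, got {n}")
    order = np.argsort(-z, kind="stable")
    base, r = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:r] += 1
    bins = np.empty(n, dtype=int)
    bins[order] = np.repeat(np.arange(1, n_bins + 1), sizes)
    edges = np.cumsum(sizes)[:-1]
    boundaries = z[order][edges - 1]  # lowest z inside each of the first n_bins-1 bins
    return DecileAssignment(bin=bins, boundaries=boundaries)


def risk_proportions(
    assignment: DecileAssignment,
    domain_scores: np.ndarray,
    thresholds_sd: tuple[float, ...] = DEFAULT_THRESHOLDS,
    domain: str = "domain",
) -> pd.DataFrame:
    """Per-bin counts/proportions of subjects above mean + t*SD of the domain score.

    The mean and SD are computed over the full cohort so each threshold is
    a single cutoff.
    """
    scores = np.asarray(domain_scores, dtype=float).ravel()
    if scores.size != assignment.bin.size:
        raise ValueError("domain_scores not aligned with the decile assignment")
    mu = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("domain scores have zero SD; thresholds undefined")
    rows = []
    for t in thresholds_sd:
        cutoff = mu + t * sd
        above = scores > cutoff
        for b in range(1, assignment.n_bins + 1):
            in_bin = assignment.bin == b
            n_bin = int(in_bin.sum())
            n_above = int((above & in_bin).sum())
            rows.append(
                {
                    "domain": domain,
                    "threshold": t,
                    "bin": b,
                    "n": n_bin,
                    "n_above": n_above,
                    "proportion": n_above / n_bin,
                }
            )
    return pd.DataFrame(rows)


def odds_ratio(
    exposed_cases: int,
    unexposed_noncases: int,
    exposed_noncases: int,
    unexposed_cases: int,
    correction: bool = False,
) -> float:
    """Cross-ratio (exposed_cases * unexposed_noncases) / (exposed_noncases * unexposed_cases).

    Exposure = symptom score above threshold; cases sit in the poorest-
    performance bin, noncases in the best.  A zero denominator yields NaN
    with a warning unless ``correction`` applies the Haldane-Anscombe +0.5.
    """
    cells = [exposed_cases, unexposed_noncases, exposed_noncases, unexposed_cases]
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    a, b, c, d = (float(v) for v in cells)
    if correction and (0.0 in cells):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if c * d == 0:
        logger.warning("odds ratio undefined (zero denominator cell); returning NaN")
        return float("nan")
    return (a * b) / (c * d)


def enrichment_tables(
    assignment: DecileAssignment,
    domains: pd.DataFrame,
    thresholds_sd: tuple[float, ...] = DEFAULT_THRESHOLDS,
    correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrichment proportions per (domain, threshold, bin) and worst-vs-best ORs.

    ``domains``: one column of scores per clinical domain (no subject_id
    column).  The OR compares the last (poorest-performance) bin as cases
    against bin 1 as noncases.
    """
    enrich_rows = []
    or_rows = []
    worst = assignment.n_bins
    for col in domains.columns:
        scores = domains[col].to_numpy(dtype=float)
        table = risk_proportions(assignment, scores, thresholds_sd, domain=col)
        enrich_rows.append(table)
        mu, sd = scores.mean(), scores.std(ddof=1)
        for t in thresholds_sd:
            above = scores > mu + t * sd
            cases = assignment.bin == worst
            noncases = assignment.bin == 1
            orv = odds_ratio(
                int((above & cases).sum()),
                int((~above & noncases).sum()),
                int((above & noncases).sum()),
                int((~above & cases).sum()),
                correction=correction,
            )
            or_rows.append({"domain": col, "threshold": t, "odds_ratio": orv})
    return pd.concat(enrich_rows, ignore_index=True), pd.DataFrame(or_rows)
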