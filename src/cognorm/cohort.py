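"""Synthetic cohorts with the statistical structure the analysis pipeline assumes.

A cohort bundles per-subject demographics (age, sex), a cognitive test
battery loading on a single latent factor that grows with age, ordinal
clinical items generated from a small number of latent symptom factors
correlated with the cognition residual, and (optionally) independent SNP
dosages with a GWAS-style summary-statistics table.  The latent truth is
retained so downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, stats

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "implied_age_correlation",
]

N_SYMPTOM_FACTORS = 7


def _default_test_loadings(n_tests: int) -> np.ndarray:
    """First test (the achievement-test analogue) loads highest on latent g."""
    if n_tests < 1:
        return np.empty(0)
    rest = np.linspace(0.80, 0.50, n_tests - 1) if n_tests > 1 else np.empty(0)
    return np.concatenate([[0.85], rest])


def _default_item_loadings(n_items: int, n_factors: int = N_SYMPTOM_FACTORS) -> np.ndarray:
    """Sparse block structure: each item loads 0.75 on one factor, round-robin."""
    loadings = np.zeros((n_items, n_factors))
    for i in range(n_items):
        loadings[i, i % n_factors] = 0.75
    return loadings


# Symptom-factor correlations with the cognition residual (residual oriented
# "higher = better than expected"): four factors track poorer cognition, one
# tracks slightly better, two are near-null.
_DEFAULT_SYMPTOM_EFFECT = (-0.17, -0.12, -0.13, -0.17, 0.06, -0.015, -0.03)


@dataclasses.dataclass
class CohortConfig:
    """Generative parameters for :func:`generate_cohort`.

    ``g_growth`` is ``(intercept, log-age slope, sex offset)`` for the latent
    cognition mean; ``residual_sd`` is either a constant or ``(b0, b1)`` for
    an SD linear in age.  ``symptom_effect`` gives the correlation of each
    latent symptom factor with the cognition residual.  ``item_cutpoints``
    are cumulative probabilities splitting the latent item score into
    ordinal levels.
    """

    n_subjects: int = 6481
    age_range: tuple[float, float] = (8.0, 21.0)
    female_fraction: float = 0.52
    g_growth: tuple[float, float, float] = (-4.0, 1.5, 0.2)
    residual_sd: float | tuple[float, float] = 0.5
    n_tests: int = 17
    test_loadings: Sequence[float] | None = None
    test_noise_sd: Sequence[float] | None = None
    cognitive_missing_rate: float = 0.01
    item_missing_rate: float = 0.02
    n_items: int = 129
    item_loadings: np.ndarray | None = None
    item_cutpoints: tuple[float, ...] = (0.6, 0.85)
    symptom_effect: tuple[float, ...] = _DEFAULT_SYMPTOM_EFFECT
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    # -- resolved arrays -------------------------------------------------
    def resolved_test_loadings(self) -> np.ndarray:
        if self.test_loadings is None:
            return _default_test_loadings(self.n_tests)
        return np.asarray(self.test_loadings, dtype=float)

    def resolved_test_noise_sd(self) -> np.ndarray:
        if self.test_noise_sd is None:
            lam = self.resolved_test_loadings()
            return np.sqrt(np.clip(1.0 - lam**2, 0.0, None))
        arr = np.asarray(self.test_noise_sd, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_tests, float(arr))
        return arr

    def resolved_item_loadings(self) -> np.ndarray:
        if self.item_loadings is None:
            return _default_item_loadings(self.n_items, len(self.symptom_effect))
        return np.asarray(self.item_loadings, dtype=float)

    def residual_sd_at(self, age: np.ndarray) -> np.ndarray:
        if np.isscalar(self.residual_sd) or isinstance(self.residual_sd, (int, float)):
            return np.full_like(np.asarray(age, dtype=float), float(self.residual_sd))
        b0, b1 = self.residual_sd
        return b0 + b1 * np.asarray(age, dtype=float)

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
            raise ValueError("age_range must be finite with min < max")
        for name, p in [
            ("female_fraction", self.female_fraction),
            ("cognitive_missing_rate", self.cognitive_missing_rate),
            ("item_missing_rate", self.item_missing_rate),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not np.all(np.isfinite(self.g_growth)):
            raise ValueError("g_growth entries must be finite")
        lam = self.resolved_test_loadings()
        if lam.shape != (self.n_tests,) or not np.all(np.isfinite(lam)):
            raise ValueError("test_loadings must be n_tests finite values")
        noise = self.resolved_test_noise_sd()
        if noise.shape != (self.n_tests,) or not np.all(np.isfinite(noise)) or np.any(noise < 0):
            raise ValueError("test_noise_sd must be n_tests finite non-negative values")
        L = self.resolved_item_loadings()
        if L.shape != (self.n_items, len(self.symptom_effect)) or not np.all(np.isfinite(L)):
            raise ValueError("item_loadings must be n_items x n_factors and finite")
        if not np.all(np.isfinite(self.symptom_effect)) or np.any(np.abs(self.symptom_effect) > 1):
            raise ValueError("symptom_effect entries must be correlations in [-1, 1]")
        grid = np.linspace(lo, hi, 64)
        if np.any(self.residual_sd_at(grid) < 0) or not np.all(np.isfinite(self.residual_sd_at(grid))):
            raise ValueError("residual_sd must be non-negative over the age range")
        cuts = np.asarray(self.item_cutpoints, dtype=float)
        if cuts.size == 0 or np.any(cuts <= 0) or np.any(cuts >= 1) or np.any(np.diff(cuts) <= 0):
            raise ValueError("item_cutpoints must be strictly increasing in (0, 1)")
        m0, m1 = self.maf_range
        if not (0.0 < m0 <= m1 <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        if self.n_snps < 0 or self.n_items < 0 or self.n_tests < 0:
            raise ValueError("counts must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("test_loadings", "test_noise_sd", "item_loadings"):
            if isinstance(d[key], np.ndarray):
                d[key] = d[key].tolist()
        for key in ("age_range", "g_growth", "item_cutpoints", "symptom_effect", "maf_range"):
            d[key] = list(d[key])
        if isinstance(d["residual_sd"], tuple):
            d["residual_sd"] = list(d["residual_sd"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        for key in ("age_range", "g_growth", "item_cutpoints", "symptom_effect", "maf_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if isinstance(kwargs.get("residual_sd"), (list, tuple)):
            kwargs["residual_sd"] = tuple(kwargs["residual_sd"])
        if kwargs.get("item_loadings") is not None:
            kwargs["item_loadings"] = np.asarray(kwargs["item_loadings"], dtype=float)
        return cls(**kwargs)


@dataclasses.dataclass
class SyntheticCohort:
    """Generated cohort blocks, all indexed by ``subject_id`` row order."""

    demographics: pd.DataFrame  # subject_id, age, sex
    cognition: pd.DataFrame  # subject_id + test columns, NaN = missing
    clinical_items: pd.DataFrame  # subject_id + item columns, NaN = missing
    genotypes: pd.DataFrame  # subject_id + SNP dosage columns
    summary_stats: pd.DataFrame  # snp_id, beta, p_value
    truth: pd.DataFrame  # subject_id, g, residual, factor_*
    config: CohortConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.demographics)

    def validate(self) -> None:
        n = self.n_subjects
        for name in ("cognition", "clinical_items", "genotypes", "truth"):
            block = getattr(self, name)
            if len(block) != n:
                raise ValueError(f"{name} has {len(block)} rows, expected {n}")
        if len(self.genotypes.columns) > 1:
            dos = self.genotypes.drop(columns="subject_id").to_numpy(dtype=float)
            if dos.size and (np.nanmin(dos) < 0 or np.nanmax(dos) > 2):
                raise ValueError("dosages must lie in [0, 2]")
        if len(self.summary_stats):
            p = self.summary_stats["p_value"].to_numpy(dtype=float)
            if np.any(p <= 0) or np.any(p > 1):
                raise ValueError("p_values must lie in (0, 1]")

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            demographics=self.demographics.copy(),
            cognition=self.cognition.copy(),
            clinical_items=self.clinical_items.copy(),
            genotypes=self.genotypes.copy(),
            summary_stats=self.summary_stats.copy(),
            truth=self.truth.copy(),
            config=self.config,
        )


def _standardize_or_zero(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        return x.copy()
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def test_names(n_tests: int) -> list[str]:
    """Column labels for the cognitive block; the first is the anchor test."""
    return ["WRAT"] + [f"CT{i:02d}" for i in range(1, n_tests)]


def item_names(n_items: int) -> list[str]:
    return [f"item_{i:03d}" for i in range(1, n_items + 1)]


def snp_names(n_snps: int) -> list[str]:
    return [f"rs{i:06d}" for i in range(1, n_snps + 1)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config`` (fully seed-determined)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range

    age = rng.uniform(lo, hi, size=n)
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    subject_id = [f"S{i:06d}" for i in range(1, n + 1)]

    a, b, c = config.g_growth
    g_mean = a + b * np.log(age) + c * sex
    sd_age = config.residual_sd_at(age)
    residual = rng.standard_normal(n) * sd_age
    g = g_mean + residual

    # symptom factors correlated with the standardized cognition residual
    s = np.asarray(config.symptom_effect, dtype=float)
    k = s.size
    eps_std = _standardize_or_zero(residual)
    eta = rng.standard_normal((n, k))
    factors = eps_std[:, None] * s[None, :] + eta * np.sqrt(1.0 - s**2)[None, :]

    # cognitive battery: shared latent factor + specific noise
    lam = config.resolved_test_loadings()
    noise_sd = config.resolved_test_noise_sd()
    g_std = _standardize_or_zero(g)
    tests = g_std[:, None] * lam[None, :] + rng.standard_normal((n, config.n_tests)) * noise_sd[None, :]

    # ordinal items: latent Gaussian combination of factors, quantile-cut
    L = config.resolved_item_loadings()
    row_norm = np.sqrt(np.sum(L**2, axis=1))
    unique_sd = np.sqrt(np.clip(1.0 - row_norm**2, 0.0, None))
    item_latent = factors @ L.T + rng.standard_normal((n, config.n_items)) * unique_sd[None, :]
    cutz = stats.norm.ppf(np.asarray(config.item_cutpoints, dtype=float))
    items = np.digitize(item_latent, cutz).astype(float)

    # independent SNPs, null summary statistics
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    dosages = rng.binomial(2, maf, size=(n, config.n_snps)).astype(float)
    beta = rng.normal(0.0, 0.05, size=config.n_snps)
    p_value = 1.0 - rng.random(config.n_snps)  # in (0, 1]

    cognition = pd.DataFrame(tests, columns=test_names(config.n_tests))
    cognition.insert(0, "subject_id", subject_id)
    clinical = pd.DataFrame(items, columns=item_names(config.n_items))
    clinical.insert(0, "subject_id", subject_id)
    genotypes = pd.DataFrame(dosages, columns=snp_names(config.n_snps))
    genotypes.insert(0, "subject_id", subject_id)
    truth = pd.DataFrame({"subject_id": subject_id, "g": g, "residual": residual})
    for j in range(k):
        truth[f"factor_{j + 1}"] = factors[:, j]

    cohort = SyntheticCohort(
        demographics=pd.DataFrame({"subject_id": subject_id, "age": age, "sex": sex}),
        cognition=cognition,
        clinical_items=clinical,
        genotypes=genotypes,
        summary_stats=pd.DataFrame(
            {"snp_id": snp_names(config.n_snps), "beta": beta, "p_value": p_value}
        ),
        truth=truth,
        config=config,
    )
    if config.cognitive_missing_rate > 0 or config.item_missing_rate > 0:
        if config.cognitive_missing_rate >= 1 or config.item_missing_rate >= 1:
            raise ValueError("missing rates must be < 1")
        cohort = inject_missingness(
            cohort,
            cognitive_rate=config.cognitive_missing_rate,
            item_rate=config.item_missing_rate,
            seed=config.seed + 1,
        )
    cohort.validate()
    return cohort


def inject_missingness(
    cohort: SyntheticCohort,
    cognitive_rate: float,
    item_rate: float,
    seed: int,
) -> SyntheticCohort:
    """Set cells missing completely at random; the truth block is untouched."""
    for name, rate in [("cognitive_rate", cognitive_rate), ("item_rate", item_rate)]:
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{name} must lie in [0, 1), got {rate}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for block_name, rate in [("cognition", cognitive_rate), ("clinical_items", item_rate)]:
        if rate == 0:
            continue
        block = getattr(out, block_name)
        values = block.drop(columns="subject_id").to_numpy(dtype=float)
        mask = rng.random(values.shape) < rate
        values[mask] = np.nan
        block.iloc[:, 1:] = values
    return out


def implied_age_correlation(config: CohortConfig) -> float:
    """Correlation between latent g and age implied by the generative model.

    Age is uniform on its range, sex independent of age, so the only
    age-linked term is the log-age trend; residual variance is averaged
    over the age distribution.
    """
    lo, hi = config.age_range
    _, b, c = config.g_growth
    width = hi - lo

    def _mean(f):
        return integrate.quad(f, lo, hi)[0] / width

    e_age = _mean(lambda a: a)
    e_log = _mean(np.log)
    cov_age_log = _mean(lambda a: a * np.log(a)) - e_age * e_log
    var_age = _mean(lambda a: a**2) - e_age**2
    var_log = _mean(lambda a: np.log(a) ** 2) - e_log**2
    p = config.female_fraction
    var_sex = p * (1 - p)
    e_res_var = _mean(lambda a: float(config.residual_sd_at(np.asarray([a]))[0]) ** 2)
    var_g = b**2 * var_log + c**2 * var_sex + e_res_var
    if var_g == 0:
        raise ValueError("degenerate config: latent g has zero variance")
    return b * cov_age_log / np.sqrt(var_g * var_age)


# ---------------------------------------------------------------------------
# TSV persistence (missing values as empty fields)
# ---------------------------------------------------------------------------

_BLOCK_FILES = {
    "demographics": "demographics.tsv",
    "cognition": "cognition.tsv",
    "clinical_items": "clinical_items.tsv",
    "genotypes": "genotypes.tsv",
    "summary_stats": "summary_stats.tsv",
    "truth": "truth.tsv",
}


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _BLOCK_FILES.items():
        getattr(cohort, attr).to_csv(directory / fname, sep="\t", index=False, na_rep="")
    if cohort.config is not None:
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    return directory


def read_cohort(directory: str | Path) -> SyntheticCohort:
    directory = Path(directory)
    blocks = {}
    for attr, fname in _BLOCK_FILES.items():
        blocks[attr] = pd.read_csv(directory / fname, sep="\t")
    config = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = CohortConfig.from_dict(yaml.safe_load(fh))
    return SyntheticCohort(config=config, **blocks)
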