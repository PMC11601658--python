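"""Phenotype containers and trait preprocessing.

Quantitative traits are residualised on covariates, rank inverse-normal
transformed and standardised before any tail diagnostic is run; polygenic
scores are standardised alongside.  Extreme outliers (default: six or more
standard deviations from the mean) are masked out before transformation so a
handful of data-entry errors cannot masquerade as tail architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "preprocess_trait",
    "rank_inverse_normal",
    "trait_qc",
    "TraitQCReport",
]


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Blom rank inverse-normal scores, Phi^-1((r - 3/8) / (n + 1/4)).

    Ties receive average ranks, so tied inputs map to identical scores.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate trait: zero variance")
    return (x - x.mean()) / sd


def preprocess_trait(
    raw_values: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    sd_cutoff: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask outliers, residualise on covariates, and RINT-standardise.

    Parameters
    ----------
    raw_values
        Raw trait measurements (finite entries are used; NaN entries are
        masked out up front).
    covariates
        Optional (n, k) design matrix; an intercept column is added
        internally and residuals of an OLS fit replace the values.
    sd_cutoff
        Entries further than this many sample SDs from the sample mean are
        excluded (default 6).

    Returns
    -------
    (scores, mask)
        ``scores`` are mean-0/SD-1 rank inverse-normal values for the kept
        rows; ``mask`` is a boolean inclusion vector over the input rows.
    """
    raw_values = np.asarray(raw_values, dtype=float)
    if sd_cutoff <= 0:
        raise ValueError("sd_cutoff must be positive")
    finite = np.isfinite(raw_values)
    if finite.sum() < 10:
        raise ValueError("need at least 10 finite trait values")
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != raw_values.shape[0]:
            raise ValueError(
                "covariate matrix has %d rows, expected %d"
                % (covariates.shape[0], raw_values.shape[0])
            )
    vals = raw_values[finite]
    if np.all(vals == vals[0]):
        raise ValueError("degenerate trait: all values identical")
    mu, sd = vals.mean(), vals.std(ddof=0)
    mask = finite.copy()
    if sd > 0:
        mask[finite] = np.abs(vals - mu) < sd_cutoff * sd
    kept = raw_values[mask]
    if kept.size < 10:
        raise ValueError("fewer than 10 values remain after outlier masking")
    if covariates is not None:
        X = np.column_stack([np.ones(mask.sum()), covariates[mask]])
        beta, *_ = np.linalg.lstsq(X, kept, rcond=None)
        kept = kept - X @ beta
    scores = rank_inverse_normal(kept)
    return _standardize(scores), mask


@dataclass
class TraitQCReport:
    """Distributional screen applied to a raw trait before analysis."""

    distinct_count: int
    top2_modal_mass: float
    skew: float
    pass_distinct: bool
    pass_modal: bool
    pass_skew: bool

    @property
    def passed(self) -> bool:
        return self.pass_distinct and self.pass_modal and self.pass_skew


def trait_qc(
    raw_values: np.ndarray,
    min_distinct: int = 10,
    max_modal_mass: float = 0.5,
    max_abs_skew: float = 2.0,
) -> TraitQCReport:
    """Check a raw trait is quantitative enough for tail analysis.

    Requires at least ``min_distinct`` distinct values, the two most common
    values together covering less than half the sample, and absolute sample
    skew at most ``max_abs_skew``.
    """
    raw_values = np.asarray(raw_values, dtype=float)
    raw_values = raw_values[np.isfinite(raw_values)]
    if raw_values.size == 0:
        raise ValueError("empty trait vector")
    _, counts = np.unique(raw_values, return_counts=True)
    distinct = counts.size
    top2 = np.sort(counts)[::-1][:2].sum() / raw_values.size
    skew = float(stats.skew(raw_values)) if distinct > 1 else 0.0
    return TraitQCReport(
        distinct_count=int(distinct),
        top2_modal_mass=float(top2),
        skew=skew,
        pass_distinct=distinct >= min_distinct,
        pass_modal=top2 < max_modal_mass,
        pass_skew=abs(skew) <= max_abs_skew,
    )


@dataclass
class PhenotypeTable:
    """Per-individual trait / PRS table used by every population-level test.

    ``trait`` and ``prs`` are standardised (mean 0, SD 1).  Optional columns
    carry offspring counts and birth cohorts for selection inference, proxy
    fitness measures, and covariates.
    """

    individual_id: np.ndarray
    trait: np.ndarray
    prs: np.ndarray
    covariates: Optional[np.ndarray] = None
    offspring: Optional[np.ndarray] = None
    cohort: Optional[np.ndarray] = None
    proxies: dict[str, np.ndarray] = field(default_factory=dict)
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id)
        self.trait = np.asarray(self.trait, dtype=float)
        self.prs = np.asarray(self.prs, dtype=float)
        n = self.trait.size
        if self.prs.size != n or self.individual_id.size != n:
            raise ValueError("column lengths differ")
        if np.unique(self.individual_id).size != n:
            raise ValueError("individual_id values are not unique")
        if not (np.isfinite(self.trait).all() and np.isfinite(self.prs).all()):
            raise ValueError("missing values in trait or prs")

    def __len__(self) -> int:
        return self.trait.size

    @property
    def n(self) -> int:
        return self.trait.size

    def standardized(self) -> "PhenotypeTable":
        """Return a copy with trait and prs re-standardised to mean 0, SD 1."""
        return PhenotypeTable(
            individual_id=self.individual_id,
            trait=_standardize(self.trait),
            prs=_standardize(self.prs),
            covariates=self.covariates,
            offspring=self.offspring,
            cohort=self.cohort,
            proxies=self.proxies,
            annotations=self.annotations,
        )

    def subset(self, idx: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(
            individual_id=self.individual_id[idx],
            trait=self.trait[idx],
            prs=self.prs[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            offspring=None if self.offspring is None else self.offspring[idx],
            cohort=None if self.cohort is None else np.asarray(self.cohort)[idx],
            proxies={k: v[idx] for k, v in self.proxies.items()},
            annotations={k: v[idx] for k, v in self.annotations.items()},
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"IID": self.individual_id, "TRAIT": self.trait, "PRS": self.prs}
        )
        if self.offspring is not None:
            out["OFFSPRING"] = self.offspring
        if self.cohort is not None:
            out["COHORT"] = self.cohort
        for name, col in self.proxies.items():
            out[f"PROXY_{name}"] = col
        if self.covariates is not None:
            for j in range(self.covariates.shape[1]):
                out[f"COV_{j + 1}"] = self.covariates[:, j]
        return out
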