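"""Selection inference from relative lifetime reproductive success (rLRS).

Offspring counts are normalised by birth-cohort means to give each
individual a relative lifetime reproductive success Y_rLRS.  Regressing
Y_rLRS on the standardised trait z with the model

    Y_rLRS = beta0 + beta * z + gamma * z^2

and selecting among the four intercept-containing submodels by BIC yields a
selection category per trait: no selection, positive/negative (sign of the
linear term), stabilising (quadratic only, gamma < 0) or disruptive
(gamma > 0).  Downstream contrasts relate those categories, and tail means
of broad fitness proxies, to POPout tail effects.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "relative_lrs",
    "CandidateFit",
    "SelectionFit",
    "fit_selection_models",
    "classify_selection",
    "tail_effect_contrast",
    "fitness_proxy_association",
]

#: candidate submodels of the quadratic rLRS regression (terms beyond the intercept)
_CANDIDATES: tuple[tuple[str, ...], ...] = (
    (),
    ("linear",),
    ("quadratic",),
    ("linear", "quadratic"),
)


def relative_lrs(offspring: Sequence[int], cohort: Sequence) -> np.ndarray:
    """Offspring count divided by the birth-cohort mean.

    The within-cohort mean of the output is exactly 1, making rLRS
    comparable across cohorts with secular fertility differences.
    """
    offspring = np.asarray(offspring, dtype=float)
    cohort = np.asarray(cohort)
    if offspring.size != cohort.size:
        raise ValueError("offspring and cohort lengths differ")
    if np.any(offspring < 0) or not np.isfinite(offspring).all():
        raise ValueError("offspring counts must be finite and non-negative")
    out = np.empty_like(offspring)
    for c in np.unique(cohort):
        rows = cohort == c
        if rows.sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 members")
        m = offspring[rows].mean()
        if m <= 0:
            raise ValueError(f"cohort {c!r} has zero mean offspring count")
        out[rows] = offspring[rows] / m
    return out


@dataclass
class CandidateFit:
    included_terms: tuple[str, ...]
    beta0: float
    beta: Optional[float]
    gamma: Optional[float]
    rss: float
    bic: float


@dataclass
class SelectionFit:
    candidate_models: list[CandidateFit]
    best_model: int
    category: str
    perfect_fit: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def best(self) -> CandidateFit:
        return self.candidate_models[self.best_model]


def fit_selection_models(rlrs: Sequence[float], trait: Sequence[float]) -> SelectionFit:
    """Fit the four rLRS submodels by least squares and select by BIC.

    BIC is the Gaussian profile form n*ln(RSS/n) + k*ln(n), with k counting
    regression parameters including the intercept.  An exact (RSS = 0) fit
    short-circuits model selection and is flagged as a perfect fit.
    """
    y = np.asarray(rlrs, dtype=float)
    z = np.asarray(trait, dtype=float)
    if y.size != z.size:
        raise ValueError("rlrs and trait lengths differ")
    n = y.size
    cols = {"linear": z, "quadratic": z * z}
    fits: list[CandidateFit] = []
    perfect = None
    for terms in _CANDIDATES:
        k = 1 + len(terms)
        if n <= k:
            raise ValueError("fewer observations than parameters")
        X = np.column_stack([np.ones(n)] + [cols[t] for t in terms])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if rss <= 1e-12 * max(1.0, float(np.sum(y * y))):
            bic = -np.inf
            if perfect is None:
                perfect = len(fits)
        else:
            bic = n * np.log(rss / n) + k * np.log(n)
        beta = coef[1 + terms.index("linear")] if "linear" in terms else None
        gamma = coef[1 + terms.index("quadratic")] if "quadratic" in terms else None
        fits.append(
            CandidateFit(
                included_terms=terms,
                beta0=float(coef[0]),
                beta=None if beta is None else float(beta),
                gamma=None if gamma is None else float(gamma),
                rss=rss,
                bic=float(bic),
            )
        )
    # perfect fits tie at BIC -inf; prefer the most parsimonious one
    best = perfect if perfect is not None else int(np.argmin([f.bic for f in fits]))
    fit = SelectionFit(
        candidate_models=fits,
        best_model=best,
        category="",
        perfect_fit=perfect is not None,
        flags=["perfect-fit"] if perfect is not None else [],
    )
    fit.category = classify_selection(fit)
    return fit


def classify_selection(fit: SelectionFit) -> str:
    """Map the BIC-selected rLRS model to a selection category.

    Intercept-only: none.  Linear-only: positive if beta > 0 else negative.
    Quadratic-only: stabilising if gamma < 0 else disruptive.  Both terms:
    the linear term gives the general direction (positive/negative).
    """
    best = fit.candidate_models[fit.best_model]
    terms = set(best.included_terms)
    if not terms:
        return "none"
    if terms == {"linear"}:
        return "positive" if best.beta > 0 else "negative"
    if terms == {"quadratic"}:
        return "stabilising" if best.gamma < 0 else "disruptive"
    return "positive" if best.beta > 0 else "negative"


#: grouping of per-trait categories into the four contrast groups
_CONTRAST_GROUPS = {
    "none": "none",
    "stabilising": "stabilising",
    "disruptive": "stabilising",  # non-directional quadratic selection
    "positive": "positive",
    "negative": "negative",
}


def tail_effect_contrast(
    lower_effects: Sequence[float],
    upper_effects: Sequence[float],
    lower_significant: Sequence[bool],
    upper_significant: Sequence[bool],
    categories: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Welch t-test of lower vs upper significant POPout effects per group.

    Traits are grouped by selection category (none; non-directional
    stabilising; positive-direction; negative-direction).  Within each
    group, the mean significant lower-tail effect is contrasted with the
    mean significant upper-tail effect.  Directional selection predicts the
    selected-against tail carries the larger effect.  Groups with fewer than
    two significant effects in either tail are skipped with a warning.
    """
    lower_effects = np.asarray(lower_effects, dtype=float)
    upper_effects = np.asarray(upper_effects, dtype=float)
    lower_significant = np.asarray(lower_significant, dtype=bool)
    upper_significant = np.asarray(upper_significant, dtype=bool)
    categories = np.asarray([_CONTRAST_GROUPS.get(c, c) for c in categories])
    out: dict[str, dict[str, float]] = {}
    for group in ("none", "stabilising", "positive", "negative"):
        rows = categories == group
        if not rows.any():
            continue
        lo = lower_effects[rows & lower_significant]
        up = upper_effects[rows & upper_significant]
        if lo.size < 2 or up.size < 2:
            _warnings.warn(f"category {group!r}: fewer than 2 significant effects per tail; skipped")
            continue
        if np.ptp(lo) == 0 and np.ptp(up) == 0 and lo.mean() == up.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(lo, up, equal_var=False)
        out[group] = {
            "lower_mean": float(lo.mean()),
            "upper_mean": float(up.mean()),
            "n_lower": int(lo.size),
            "n_upper": int(up.size),
            "t": float(t),
            "p": float(p),
        }
    return out


def fitness_proxy_association(
    tables,
    proxy_name: str,
    lower_effects: Sequence[float],
    upper_effects: Sequence[float],
    tail_fraction: float = 0.01,
) -> tuple[float, float]:
    """Spearman correlation of tail-mean fitness proxies with POPout effects.

    For each trait table, the mean of the named proxy measure is computed
    among the individuals in the lower and upper ``tail_fraction`` trait
    tails; these per-trait-tail means are rank-correlated against the
    matching POPout effect sizes across all trait-tails.
    """
    lower_effects = np.asarray(lower_effects, dtype=float)
    upper_effects = np.asarray(upper_effects, dtype=float)
    tables = list(tables)
    if len(tables) != lower_effects.size or len(tables) != upper_effects.size:
        raise ValueError("one effect per table per tail required")
    means, effects = [], []
    for table, lo_eff, up_eff in zip(tables, lower_effects, upper_effects):
        proxy = table.proxies.get(proxy_name)
        if proxy is None:
            raise ValueError(f"proxy {proxy_name!r} missing from table")
        order = np.argsort(table.trait, kind="stable")
        n_tail = max(1, int(tail_fraction * len(table)))
        means.append(float(np.mean(proxy[order[:n_tail]])))
        effects.append(lo_eff)
        means.append(float(np.mean(proxy[order[-n_tail:]])))
        effects.append(up_eff)
    if len(means) < 5:
        raise ValueError("need at least 5 trait-tail pairs")
    if np.ptp(means) == 0:
        raise ValueError("constant proxy: ranks undefined")
    rho, p = stats.spearmanr(means, effects)
    return float(rho), float(p)
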