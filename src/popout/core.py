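"""The POPout test: PRS regression-to-the-mean diagnostics in trait tails.

A polygenic score built from common variants should relate linearly to its
trait across the whole distribution.  If rare, large-effect alleles are
concentrated in a tail, the observed PRS of tail individuals sits closer to
the population mean than the value predicted by the PRS-on-trait regression.
The POPout effect quantifies this as the mean of |f(y_i)| - |PRS_i| over the
tail, with f the fitted regression line, and a one-sample t-test on the tail
residuals supplies the significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phenotypes import PhenotypeTable

__all__ = ["TailResult", "PopoutResult", "popout_test", "popout_qc", "bh_fdr"]

#: default Bonferroni level of the middle-centile screen (80 tests)
QC_ALPHA = 0.05
N_QC_CENTILES = 80


@dataclass
class TailResult:
    tail: str  # "lower" | "upper"
    n: int
    effect: float
    t_statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)


@dataclass
class PopoutResult:
    slope: float
    intercept: float
    tail_fraction: float
    lower: TailResult
    upper: TailResult
    qc_centile_p: Optional[np.ndarray] = None
    qc_pass: Optional[bool] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def tails(self) -> tuple[TailResult, TailResult]:
        return (self.lower, self.upper)


def _one_sample_t(residuals: np.ndarray) -> tuple[float, float, list[str]]:
    """Two-sided one-sample t-test for zero mean; df = n - 1.

    Zero-variance residuals (e.g. PRS identical to trait) make the statistic
    undefined; those are reported as t=0, p=1 with a flag.
    """
    n = residuals.size
    sd = residuals.std(ddof=1) if n > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return 0.0, 1.0, ["zero-variance-residuals"]
    t = residuals.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), []


def _centile_bins(order: np.ndarray, n_bins: int = 100) -> list[np.ndarray]:
    """Split trait-ranked row indices into ``n_bins`` equal-count bins.

    Remainder rows from N mod n_bins go to the lowest-index bins.
    """
    n = order.size
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    edges = np.cumsum([0] + sizes)
    return [order[edges[i] : edges[i + 1]] for i in range(n_bins)]


def popout_qc(
    table: PhenotypeTable,
    min_per_centile: int = 80,
    residuals: Optional[np.ndarray] = None,
    order: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, bool]:
    """Middle-80-centile screen on the PRS-on-trait regression residuals.

    Rows are ranked by trait into 100 equal-count bins; centiles 11-90 are
    each tested for zero mean residual (two-sided t).  A trait fails if the
    smallest of the 80 p-values is significant at the Bonferroni-corrected
    0.05 level (p <= 0.05/80) — a linear PRS-trait relation must hold in the
    bulk of the distribution for the tail test to be interpretable.
    """
    y, p = table.trait, table.prs
    if y.size < 100 * min_per_centile:
        raise ValueError(
            f"popout_qc needs >= {100 * min_per_centile} rows "
            f"({min_per_centile} per centile); got {y.size}"
        )
    if residuals is None or order is None:
        if y.std(ddof=0) == 0:
            raise ValueError("zero trait variance")
        slope, intercept = np.polyfit(y, p, 1)
        residuals = p - (intercept + slope * y)
        if residuals.std(ddof=0) < 1e-10:  # PRS perfectly predicted (float noise only)
            residuals = np.zeros_like(residuals)
        order = np.argsort(y, kind="stable")
    bins = _centile_bins(order)
    pvals = np.empty(N_QC_CENTILES)
    for i, b in enumerate(bins[10:90]):
        _, pv, _ = _one_sample_t(residuals[b])
        pvals[i] = pv
    qc_pass = bool(pvals.min() > QC_ALPHA / N_QC_CENTILES)
    return pvals, qc_pass


def popout_test(
    table: PhenotypeTable,
    tail_fraction: float = 0.01,
    min_tail_n: int = 100,
    run_qc: bool = True,
    standardize: bool = True,
) -> PopoutResult:
    """Run the POPout test on both tails of a phenotype table.

    Parameters
    ----------
    table
        Standardised trait and PRS per individual.  By default both columns
        are re-standardised within the analysed sample.
    tail_fraction
        Mass of each tested tail (default 0.01: bottom and top 1%).
    min_tail_n
        Floor on the per-tail sample size (default 100).
    run_qc
        Also compute the middle-80-centile screen when the sample is large
        enough (>= 8,000 rows at the default floor); smaller samples leave
        the QC fields unset.

    Returns
    -------
    PopoutResult
        Regression fit, per-tail effect / t / p, and QC centile p-values.

    Notes
    -----
    Tail membership is rank-based: the floor(tail_fraction * N) smallest and
    largest trait values, ties broken by stable input order.  A positive
    effect means the observed PRS regresses toward the population mean
    relative to the linear prediction.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if standardize:
        table = table.standardized()
    y, p = table.trait, table.prs
    n_total = y.size
    n_tail = int(math.floor(tail_fraction * n_total))
    if n_tail < min_tail_n:
        raise ValueError(
            f"each tail needs >= {min_tail_n} individuals; "
            f"tail_fraction {tail_fraction} of N={n_total} gives {n_tail}"
        )
    if y.std(ddof=0) == 0:
        raise ValueError("zero trait variance")

    slope, intercept = np.polyfit(y, p, 1)
    warnings: list[str] = []
    if slope < 0:
        warnings.append("negative trait-PRS slope")
    fitted = intercept + slope * y
    residuals = p - fitted
    if residuals.std(ddof=0) < 1e-10:  # PRS perfectly predicted (float noise only)
        residuals = np.zeros_like(residuals)
    order = np.argsort(y, kind="stable")

    tails = {}
    for name, idx in (("lower", order[:n_tail]), ("upper", order[-n_tail:])):
        effect = float(np.mean(np.abs(fitted[idx]) - np.abs(p[idx])))
        t, pv, flags = _one_sample_t(residuals[idx])
        tails[name] = TailResult(
            tail=name, n=n_tail, effect=effect, t_statistic=t, p_value=pv, flags=flags
        )

    qc_p, qc_pass = None, None
    if run_qc and n_total >= 8000:
        qc_p, qc_pass = popout_qc(table, residuals=residuals, order=order)

    return PopoutResult(
        slope=float(slope),
        intercept=float(intercept),
        tail_fraction=tail_fraction,
        lower=tails["lower"],
        upper=tails["upper"],
        qc_centile_p=qc_p,
        qc_pass=qc_pass,
        warnings=warnings,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
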