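"""Case/control PRS prediction emulation and its polygenic baseline.

A quantitative trait is dichotomised at a quantile (e.g. the top 25% or top
1% become "cases", mimicking a clinical threshold such as obesity on BMI)
and the PRS is scored by the odds ratio of each PRS quantile bin against the
central bin.  The matched baseline simulates a trait T = r*PRS + E with the
same PRS r^2 under uniform polygenicity, giving the OR curve the score
*should* produce if no tail architecture is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import _centile_bins
from .phenotypes import PhenotypeTable

__all__ = ["ORCurve", "emulate_case_control_or", "expected_or_curve"]

_Z95 = 1.959963984540054


@dataclass
class ORCurve:
    case_quantile: float
    bin_edges: np.ndarray  # PRS values delimiting the equal-count bins
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference_bin: int
    haldane_flags: np.ndarray  # bins where a zero cell was 0.5-corrected
    tail_mean_or: dict[str, float] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.odds_ratio.size


def _bin_or(case: np.ndarray, j_rows: np.ndarray, ref: np.ndarray):
    """OR of bin j vs the reference bin with a 95% Wald CI.

    For a single binary bin indicator the logistic-regression MLE equals the
    2x2-table odds ratio, so the table form is computed directly.  Zero cells
    get the Haldane 0.5 correction and are flagged.
    """
    a = case[j_rows].sum()  # cases in bin
    b = j_rows.size - a  # controls in bin
    c = case[ref].sum()  # cases in reference
    d = ref.size - c
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("bin with zero cases and zero controls")
    flag = 0
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flag = 1
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), math.exp(log_or - _Z95 * se), math.exp(log_or + _Z95 * se), flag


def emulate_case_control_or(
    table: PhenotypeTable,
    case_quantile: float = 0.75,
    n_bins: int = 100,
) -> ORCurve:
    """Quantile OR curve of the PRS against a dichotomised trait.

    ``case_quantile`` above 0.5 defines cases as trait values beyond the
    upper quantile; below 0.5, beyond the lower quantile.  The PRS is cut
    into ``n_bins`` equal-count bins and each bin's OR against the bin
    containing the median PRS is reported, with 95% Wald CIs.  The mean OR
    over the extreme 5% of PRS bins at each end is summarised in
    ``tail_mean_or``.
    """
    if not 0 < case_quantile < 1:
        raise ValueError("case_quantile must be in (0, 1)")
    y, p = table.trait, table.prs
    thr = np.quantile(y, case_quantile)
    case = (y > thr) if case_quantile >= 0.5 else (y < thr)
    case = case.astype(np.int64)

    order = np.argsort(p, kind="stable")
    bins = _centile_bins(order, n_bins)
    # reference = bin holding the median-ranked PRS value
    median_rank = (p.size - 1) // 2
    sizes = np.array([b.size for b in bins])
    ref_bin = int(np.searchsorted(np.cumsum(sizes), median_rank, side="right"))
    ref_rows = bins[ref_bin]

    ors = np.empty(n_bins)
    lo = np.empty(n_bins)
    hi = np.empty(n_bins)
    flags = np.zeros(n_bins, dtype=bool)
    for j, rows in enumerate(bins):
        if j == ref_bin:
            ors[j], lo[j], hi[j], flags[j] = 1.0, 1.0, 1.0, False
            continue
        ors[j], lo[j], hi[j], fl = _bin_or(case, rows, ref_rows)
        flags[j] = bool(fl)

    edges = np.array([p[b[0]] for b in bins] + [p[bins[-1][-1]]])
    k = max(1, n_bins // 20)  # extreme 5% of bins
    tail_mean = {
        "bottom": float(ors[:k].mean()),
        "top": float(ors[-k:].mean()),
    }
    return ORCurve(
        case_quantile=case_quantile,
        bin_edges=edges,
        odds_ratio=ors,
        ci_low=lo,
        ci_high=hi,
        reference_bin=ref_bin,
        haldane_flags=flags,
        tail_mean_or=tail_mean,
    )


def expected_or_curve(
    r2: float,
    n: int,
    case_quantile: float = 0.75,
    n_bins: int = 100,
    seed: int = 0,
) -> ORCurve:
    """Expected OR curve under uniform polygenicity at a given PRS r^2.

    Simulates PRS ~ N(0,1), E ~ N(0, 1-r2) and T = sqrt(r2)*PRS + E (so T is
    standard normal and the PRS explains r2 of its variance), then scores the
    simulated pair exactly as the observed data.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    prs = rng.standard_normal(n)
    trait = math.sqrt(r2) * prs + rng.normal(0.0, math.sqrt(1 - r2), n)
    table = PhenotypeTable(
        individual_id=np.arange(n), trait=trait, prs=prs
    )
    return emulate_case_control_or(table, case_quantile=case_quantile, n_bins=n_bins)
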