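"""Replication power of the POPout test in smaller target cohorts.

Repeatedly subsamples the full table at a range of sizes, reruns the tail
test, and records how often tails that are significant in the full data (at
FDR 5%) replicate at nominal p < 0.05, alongside the correlation between
subset and full-data effect sizes.  This mirrors the question of how large a
replication cohort must be for a discovered tail effect to re-appear.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PopoutResult, bh_fdr, popout_test
from .phenotypes import PhenotypeTable

__all__ = ["BootstrapPowerResult", "bootstrap_power"]


@dataclass
class BootstrapPowerResult:
    subset_sizes: np.ndarray
    replication_rate: np.ndarray  # NaN where no tail is significant at FDR 5%
    effect_correlation: np.ndarray
    full_result: PopoutResult
    n_boot: int
    fdr_level: float
    skipped_sizes: list[int]


def bootstrap_power(
    table: PhenotypeTable,
    subset_sizes,
    n_boot: int = 100,
    tail_fraction: float = 0.01,
    seed: int = 0,
    fdr_level: float = 0.05,
    min_tail_n: int = 10,
) -> BootstrapPowerResult:
    """Estimate POPout replication power across subset sizes.

    For each size, draws ``n_boot`` subsets without replacement, runs
    :func:`popout_test` on each, and records (a) the fraction of
    full-data-significant tails replicating at nominal p < 0.05 and (b) the
    Pearson correlation of subset effects with full-data effects pooled over
    both tails and all draws.  Sizes too small to hold ``min_tail_n``
    individuals per tail are skipped with a warning.
    """
    subset_sizes = np.asarray(subset_sizes, dtype=int)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(table)
    if subset_sizes.max() > n:
        raise ValueError("subset size exceeds table size")
    rng = np.random.default_rng(seed)

    full = popout_test(table, tail_fraction=tail_fraction, run_qc=False)
    full_p = np.array([full.lower.p_value, full.upper.p_value])
    full_eff = np.array([full.lower.effect, full.upper.effect])
    sig = bh_fdr(full_p) < fdr_level

    rates = np.full(subset_sizes.size, np.nan)
    corrs = np.full(subset_sizes.size, np.nan)
    skipped: list[int] = []
    for i, size in enumerate(subset_sizes):
        if int(tail_fraction * size) < min_tail_n:
            _warnings.warn(
                f"subset size {size} too small for tail floor {min_tail_n}; skipped"
            )
            skipped.append(int(size))
            continue
        rep_hits, rep_total = 0, 0
        sub_effs, ref_effs = [], []
        for _ in range(n_boot):
            idx = rng.choice(n, size=size, replace=False)
            res = popout_test(
                table.subset(idx),
                tail_fraction=tail_fraction,
                run_qc=False,
                min_tail_n=min_tail_n,
            )
            sub_p = np.array([res.lower.p_value, res.upper.p_value])
            sub_e = np.array([res.lower.effect, res.upper.effect])
            rep_hits += int(np.sum(sub_p[sig] < 0.05))
            rep_total += int(sig.sum())
            sub_effs.extend(sub_e)
            ref_effs.extend(full_eff)
        if rep_total > 0:
            rates[i] = rep_hits / rep_total
        if len(sub_effs) > 1 and np.std(sub_effs) > 0 and np.std(ref_effs) > 0:
            corrs[i] = stats.pearsonr(sub_effs, ref_effs)[0]
        elif len(sub_effs) > 1 and np.allclose(sub_effs, ref_effs):
            corrs[i] = 1.0
    return BootstrapPowerResult(
        subset_sizes=subset_sizes,
        replication_rate=rates,
        effect_correlation=corrs,
        full_result=full,
        n_boot=n_boot,
        fdr_level=fdr_level,
        skipped_sizes=skipped,
    )
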