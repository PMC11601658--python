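"""Forward-in-time Wright-Fisher simulation of a fully heritable trait.

A diploid population of N individuals carries mutations on a genome of L
base pairs.  Mutation effects are drawn from a reflected gamma distribution
(shape 0.186, mean 0.01026, sign flipped with probability 1/2), the trait of
an individual is the sum of effects over both haplotypes (h2 = 1), and the
population evolves neutrally to equilibrium (10N generations) before
stabilising selection is switched on for 1N generations through a Gaussian
fitness function

    f(x) = 1 + (k / sqrt(2 pi sigma^2)) * exp(-(x - mu)^2 / (2 sigma^2))

with mu and sigma frozen at the trait mean and SD at selection onset and k
the selection-strength multiplier (k = 1 "weak", k = 100 "strong", k = 0
neutral control).

Internally the population is a boolean genotype matrix over segregating
sites; fixed mutations move their effect into a scalar baseline so the
phenotype is preserved.  Configurations may be rescaled (N down, mu and
recombination up by the same factor, generations proportional to N), which
preserves theta = 4*N*mu*L; the selection multiplier k is deliberately NOT
rescaled, so printed full-scale percentages are only reproduced at full
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

from .core import _centile_bins

__all__ = [
    "SimConfig",
    "SimPopulation",
    "SimResult",
    "CentileSummary",
    "gaussian_fitness",
    "run_simulation",
    "continue_with_selection",
    "centile_architecture_summary",
    "enrichment_log_or",
    "extreme_carrier_fraction",
    "watterson_expected_sites",
]


@dataclass
class SimConfig:
    """Simulation parameters; the defaults are the full-scale study values."""

    pop_size: int = 10_000
    genome_length: int = 100_000
    mu: float = 2.36e-8
    recomb: float = 1e-8
    gamma_shape: float = 0.186
    gamma_mean: float = 0.01026
    burnin_gens: Optional[int] = None  # default 10N
    selection_gens: Optional[int] = None  # default 1N
    k: float = 1.0
    seed: int = 0
    maf_rare: float = 0.01
    maf_very_rare: float = 0.0005
    large_effect_quantile: float = 0.10

    def __post_init__(self) -> None:
        if self.burnin_gens is None:
            self.burnin_gens = 10 * self.pop_size
        if self.selection_gens is None:
            self.selection_gens = self.pop_size

    def rescaled(self, factor: int) -> "SimConfig":
        """Scale N down and mu/recomb up by ``factor`` (theta preserved)."""
        return replace(
            self,
            pop_size=self.pop_size // factor,
            mu=self.mu * factor,
            recomb=self.recomb * factor,
            burnin_gens=None,
            selection_gens=None,
        )


@dataclass
class SimPopulation:
    """Population snapshot: genotypes over segregating sites + registry.

    ``baseline`` is the phenotypic contribution of fixed mutations (each
    diploid carried two copies, so a fixation of effect e contributes 2e);
    trait of individual i = baseline + sum of effects over both haplotypes.
    """

    genotypes: np.ndarray  # (2N, S) bool
    positions: np.ndarray  # (S,) int bp
    effects: np.ndarray  # (S,) signed float
    origin_generation: np.ndarray  # (S,) int
    mutation_id: np.ndarray  # (S,) int, stable across generations
    baseline: float
    traits: np.ndarray  # (N,) float
    generation: int
    fitness_mu: Optional[float] = None
    fitness_sigma: Optional[float] = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0] // 2

    @property
    def counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=0)

    def haplotype_sets(self) -> list[set[int]]:
        """Haplotypes as ordered sets of mutation identifiers."""
        return [set(self.mutation_id[row]) for row in self.genotypes]

    def recompute_traits(self) -> np.ndarray:
        hap = self.genotypes @ self.effects
        return self.baseline + hap[0::2] + hap[1::2]


@dataclass
class SimResult:
    config: SimConfig
    burnin_snapshot: SimPopulation
    final_snapshot: SimPopulation
    log_generation: np.ndarray
    log_trait_mean: np.ndarray
    log_trait_sd: np.ndarray
    log_segregating: np.ndarray


def gaussian_fitness(x, mu: float, sigma: float, k: float):
    """Gaussian stabilising-selection fitness, 1 + k * N(mu, sigma) density.

    Maximal at x = mu; k = 0 recovers neutrality (fitness 1 everywhere).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    dens = np.exp(-((x - mu) ** 2) / (2.0 * sigma * sigma)) / math.sqrt(
        2.0 * math.pi * sigma * sigma
    )
    out = 1.0 + k * dens
    return float(out) if out.ndim == 0 else out


@njit(cache=False)
def _compact_columns(G, kept):  # pragma: no cover - jitted
    """In-place left-compaction of the kept columns (kept is sorted)."""
    n2 = G.shape[0]
    k = kept.shape[0]
    for g in range(n2):
        for j in range(k):
            G[g, j] = G[g, kept[j]]


@njit(cache=False)
def _copy_and_count(G_old, G_new, hap_idx, alt_idx, S, counts, positions,
                    cross_off, cross_cuts):  # pragma: no cover - jitted
    """Form all gametes and tally allele counts in one buffer traversal.

    Gametes without crossovers copy the chosen parental haplotype row;
    gametes with crossovers switch between the parent's two haplotypes
    according to the parity of crossover points left of each site.
    ``cross_off`` delimits each gamete's (sorted) cut positions in
    ``cross_cuts``.
    """
    n2 = hap_idx.shape[0]
    for s in range(S):
        counts[s] = 0
    for g in range(n2):
        src = hap_idx[g]
        a = cross_off[g]
        b = cross_off[g + 1]
        if a == b:
            for s in range(S):
                v = G_old[src, s]
                G_new[g, s] = v
                counts[s] += v
        else:
            alt = alt_idx[g]
            for s in range(S):
                pos = positions[s]
                c = 0
                for j in range(a, b):
                    if cross_cuts[j] < pos:
                        c += 1
                    else:
                        break
                v = G_old[alt, s] if (c & 1) else G_old[src, s]
                G_new[g, s] = v
                counts[s] += v


class _Population:
    """Mutable simulation state (snapshot-able into SimPopulation).

    The genotype matrix lives in a pair of pre-allocated (2N, capacity)
    uint8 buffers that swap roles each generation; ``S`` columns are active.
    Lost and fixed columns are compacted away every ``_COMPACT`` generations
    (a column that fixes stays fixed, so deferral is exact); per-site
    carrier counts come for free from the copy kernel, so segregating-site
    logs are exact every generation.  Per-haplotype trait scores are
    maintained incrementally and re-derived from the genotype matrix every
    ``_RESYNC`` generations to bound float drift.  ``baseline`` is the
    phenotypic contribution of fixed sites: each diploid carried two copies,
    so a fixation of effect e adds 2e to the baseline when its column leaves
    the matrix.
    """

    _COMPACT = 4
    _RESYNC = 512

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        n2 = 2 * config.pop_size
        self.cap = 2048
        self.A = np.zeros((n2, self.cap), dtype=np.uint8)
        self.B = np.zeros((n2, self.cap), dtype=np.uint8)
        self.S = 0
        self.counts_buf = np.zeros(self.cap, dtype=np.int64)
        self.occupied: set[int] = set()
        self.positions = np.zeros(0, dtype=np.int64)
        self.effects = np.zeros(0, dtype=float)
        self.origin = np.zeros(0, dtype=np.int64)
        self.mut_id = np.zeros(0, dtype=np.int64)
        self.next_id = 0
        self.baseline = 0.0
        self.generation = 0
        self.scores = np.zeros(n2)  # per-haplotype sum of carried effects
        self.fitness_mu: Optional[float] = None
        self.fitness_sigma: Optional[float] = None

    # -- views ---------------------------------------------------------------
    @property
    def G(self) -> np.ndarray:
        return self.A[:, : self.S]

    @property
    def counts(self) -> np.ndarray:
        return self.counts_buf[: self.S]

    def traits(self) -> np.ndarray:
        return self.baseline + self.scores[0::2] + self.scores[1::2]

    def seg_sites(self) -> int:
        n2 = self.A.shape[0]
        c = self.counts
        return int(np.count_nonzero((c > 0) & (c < n2)))

    def _grow(self, needed: int) -> None:
        while self.cap < needed:
            self.cap *= 2
        n2 = self.A.shape[0]
        for name in ("A", "B"):
            old = getattr(self, name)
            buf = np.zeros((n2, self.cap), dtype=np.uint8)
            buf[:, : self.S] = old[:, : self.S]
            setattr(self, name, buf)
        counts = np.zeros(self.cap, dtype=np.int64)
        counts[: self.S] = self.counts_buf[: self.S]
        self.counts_buf = counts

    def _compact(self) -> None:
        """Drop lost columns; migrate fixed columns into the baseline."""
        n2 = self.A.shape[0]
        c = self.counts
        fixed = c == n2
        keep = (c > 0) & ~fixed
        if fixed.any():
            fix_sum = self.effects[fixed].sum()
            self.baseline += 2.0 * fix_sum  # two copies per diploid
            self.scores -= fix_sum
        k = int(keep.sum())
        if k != self.S:
            _compact_columns(self.A, np.nonzero(keep)[0].astype(np.int64))
            self.counts_buf[:k] = c[keep]
            for pos in self.positions[~keep].tolist():
                self.occupied.discard(pos)
            self.positions = self.positions[keep]
            self.effects = self.effects[keep]
            self.origin = self.origin[keep]
            self.mut_id = self.mut_id[keep]
            self.S = k

    # -- core generation step ------------------------------------------------
    def step(self, k: float) -> None:
        cfg = self.cfg
        rng = self.rng
        N = cfg.pop_size
        n2 = 2 * N

        if k > 0:
            w = gaussian_fitness(self.traits(), self.fitness_mu, self.fitness_sigma, k)
            prob = w / w.sum()
            parents = rng.choice(N, size=n2, p=prob)
        else:
            parents = rng.integers(0, N, size=n2)

        start = rng.integers(0, 2, size=n2)
        n_cross = rng.poisson(cfg.recomb * (cfg.genome_length - 1), size=n2)
        n_new = rng.poisson(cfg.mu * cfg.genome_length, size=n2)
        total_new = int(n_new.sum())
        if self.S + total_new > self.cap:
            self._compact()
            if self.S + total_new > self.cap:
                self._grow(self.S + total_new)

        hap_idx = (2 * parents + start).astype(np.int64)
        alt_idx = (2 * parents + 1 - start).astype(np.int64)
        cross_off = np.zeros(n2 + 1, dtype=np.int64)
        np.cumsum(n_cross, out=cross_off[1:])
        total_cross = int(cross_off[-1])
        if total_cross:
            cross_cuts = rng.integers(1, cfg.genome_length, size=total_cross)
            for g in np.nonzero(n_cross > 1)[0]:
                cross_cuts[cross_off[g] : cross_off[g + 1]].sort()
        else:
            cross_cuts = np.zeros(0, dtype=np.int64)

        old, new = self.A, self.B
        S = self.S
        _copy_and_count(
            old, new, hap_idx, alt_idx, S, self.counts_buf, self.positions,
            cross_off, cross_cuts,
        )
        child_scores = self.scores.take(hap_idx)
        if total_cross and S:
            for g in np.nonzero(n_cross)[0]:
                child_scores[g] = self.effects @ new[g, :S]

        if total_new:
            # uniform positions; collisions with occupied sites or within the
            # batch are redrawn (approximate infinite sites)
            occupied = self.occupied
            new_pos = rng.integers(0, cfg.genome_length, size=total_new)
            for i, pos in enumerate(new_pos.tolist()):
                while pos in occupied:
                    pos = int(rng.integers(0, cfg.genome_length))
                occupied.add(pos)
                new_pos[i] = pos
            mag = rng.gamma(cfg.gamma_shape, cfg.gamma_mean / cfg.gamma_shape, total_new)
            sign = rng.choice([-1.0, 1.0], size=total_new)
            new_eff = mag * sign
            carrier = np.repeat(np.arange(n2), n_new)
            new[:, S : S + total_new] = 0
            new[carrier, S + np.arange(total_new)] = 1
            self.counts_buf[S : S + total_new] = 1
            for c, e in zip(carrier.tolist(), new_eff.tolist()):
                child_scores[c] += e

        self.generation += 1
        self.scores = child_scores
        self.A, self.B = new, old
        if total_new:
            self.S = S + total_new
            self.positions = np.concatenate([self.positions, new_pos])
            self.effects = np.concatenate([self.effects, new_eff])
            self.origin = np.concatenate(
                [self.origin, np.full(total_new, self.generation, dtype=np.int64)]
            )
            ids = np.arange(self.next_id, self.next_id + total_new, dtype=np.int64)
            self.next_id += total_new
            self.mut_id = np.concatenate([self.mut_id, ids])
        if self.generation % self._COMPACT == 0:
            self._compact()
        if self.generation % self._RESYNC == 0:
            self.scores = self.G @ self.effects

    def snapshot(self) -> SimPopulation:
        self._compact()
        return SimPopulation(
            genotypes=self.G != 0,
            positions=self.positions.copy(),
            effects=self.effects.copy(),
            origin_generation=self.origin.copy(),
            mutation_id=self.mut_id.copy(),
            baseline=self.baseline,
            traits=self.traits(),
            generation=self.generation,
            fitness_mu=self.fitness_mu,
            fitness_sigma=self.fitness_sigma,
        )


def _run_phase(pop: _Population, gens: int, k: float, log: dict) -> None:
    for _ in range(gens):
        pop.step(k)
        t = pop.traits()
        log["gen"].append(pop.generation)
        log["mean"].append(float(t.mean()))
        log["sd"].append(float(t.std(ddof=0)))
        log["seg"].append(pop.seg_sites())


def run_simulation(config: SimConfig) -> SimResult:
    """Burn in neutrally for ``burnin_gens``, then select for ``selection_gens``.

    At selection onset the trait mean and SD are frozen as the optimum mu and
    width sigma of the Gaussian fitness function.  Returns snapshots at the
    end of burn-in and at the end of selection plus a per-generation log of
    trait mean, trait SD and segregating-site count.
    """
    rng = np.random.default_rng(config.seed)
    pop = _Population(config, rng)
    log: dict = {"gen": [], "mean": [], "sd": [], "seg": []}
    _run_phase(pop, config.burnin_gens, 0.0, log)
    burnin_snap = pop.snapshot()
    t = pop.traits()
    sd = t.std(ddof=0)
    if sd == 0:
        raise ValueError("population trait SD is zero at selection onset")
    pop.fitness_mu, pop.fitness_sigma = float(t.mean()), float(sd)
    _run_phase(pop, config.selection_gens, config.k, log)
    final_snap = pop.snapshot()
    return SimResult(
        config=config,
        burnin_snapshot=burnin_snap,
        final_snapshot=final_snap,
        log_generation=np.array(log["gen"]),
        log_trait_mean=np.array(log["mean"]),
        log_trait_sd=np.array(log["sd"]),
        log_segregating=np.array(log["seg"]),
    )


def continue_with_selection(
    snapshot: SimPopulation, config: SimConfig, k: float, seed: int
) -> SimPopulation:
    """Run the selection phase from an end-of-burn-in snapshot.

    Lets several selection strengths k share one neutral burn-in (a paired
    design across k settings).  The optimum and width are frozen from the
    snapshot's trait distribution.
    """
    rng = np.random.default_rng(seed)
    pop = _Population(config, rng)
    S = snapshot.genotypes.shape[1]
    if S > pop.cap:
        pop._grow(2 * S)
    pop.S = S
    pop.A[:, :S] = snapshot.genotypes.astype(np.uint8)
    pop.counts_buf[:S] = snapshot.genotypes.sum(axis=0)
    pop.positions = snapshot.positions.copy()
    pop.occupied = set(snapshot.positions.tolist())
    pop.effects = snapshot.effects.copy()
    pop.origin = snapshot.origin_generation.copy()
    pop.mut_id = snapshot.mutation_id.copy()
    pop.next_id = int(snapshot.mutation_id.max() + 1) if snapshot.mutation_id.size else 0
    pop.baseline = snapshot.baseline
    pop.generation = snapshot.generation
    pop.scores = pop.G @ pop.effects
    t = pop.traits()
    sd = t.std(ddof=0)
    if sd == 0:
        raise ValueError("population trait SD is zero at selection onset")
    pop.fitness_mu, pop.fitness_sigma = float(t.mean()), float(sd)
    log: dict = {"gen": [], "mean": [], "sd": [], "seg": []}
    _run_phase(pop, config.selection_gens, k, log)
    return pop.snapshot()


def watterson_expected_sites(pop_size: int, mu: float, genome_length: int) -> float:
    """Neutral-equilibrium expected segregating sites, theta * a_{2N-1}."""
    theta = 4.0 * pop_size * mu * genome_length
    a = np.sum(1.0 / np.arange(1, 2 * pop_size))
    return float(theta * a)


# ---------------------------------------------------------------------------
# centile architecture summaries


@dataclass
class CentileSummary:
    """Per-centile allele-class counts and PRS diagnostics for one snapshot."""

    n_rare_alleles: np.ndarray
    n_very_rare_alleles: np.ndarray
    n_common_alleles: np.ndarray
    n_rare_large_alleles: np.ndarray
    n_very_rare_large_alleles: np.ndarray
    n_large_effect_rare_carriers: np.ndarray
    mean_trait: np.ndarray
    mean_common_prs: np.ndarray
    popout_like_effect: np.ndarray
    centile_of_individual: np.ndarray = field(repr=False, default=None)


def centile_architecture_summary(pop: SimPopulation, config: SimConfig) -> CentileSummary:
    """Stratify the population into 100 trait centiles and count allele classes.

    MAF is computed from all 2N haplotypes; rare means MAF < ``maf_rare``
    (default 1%), very rare MAF < ``maf_very_rare`` (default 0.05%), common
    MAF >= ``maf_rare``.  Large effects are the top ``large_effect_quantile``
    of |effect| among segregating mutations.  The common-variant PRS of an
    individual is the effect-weighted count of carried common alleles,
    standardised; the POPout-like effect per centile is the mean of
    |f(trait)| - |PRS| with f the least-squares fit of PRS on trait over the
    whole population (both standardised).
    """
    n2, S = pop.genotypes.shape
    N = n2 // 2
    if N < 100:
        raise ValueError("need at least 100 individuals")
    counts = pop.counts
    freq = counts / n2
    maf = np.minimum(freq, 1.0 - freq)
    rare = maf < config.maf_rare
    very_rare = maf < config.maf_very_rare
    common = ~rare
    if S:
        thr = np.quantile(np.abs(pop.effects), 1.0 - config.large_effect_quantile)
        large = np.abs(pop.effects) >= thr
    else:
        large = np.zeros(0, dtype=bool)

    dosage = (pop.genotypes[0::2].astype(np.float64) + pop.genotypes[1::2])
    def class_count(mask: np.ndarray) -> np.ndarray:
        return dosage[:, mask].sum(axis=1) if mask.any() else np.zeros(N)

    n_rare = class_count(rare)
    n_vrare = class_count(very_rare)
    n_common = class_count(common)
    n_rare_large = class_count(rare & large)
    n_vrare_large = class_count(very_rare & large)
    carrier_large_rare = (dosage[:, rare & large] > 0).any(axis=1) if (rare & large).any() else np.zeros(N, dtype=bool)

    traits = pop.traits
    prs_raw = dosage[:, common] @ pop.effects[common] if common.any() else np.zeros(N)

    def std(x: np.ndarray) -> np.ndarray:
        s = x.std(ddof=0)
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    t_std = std(traits)
    p_std = std(prs_raw)
    if t_std.std(ddof=0) > 0 and p_std.std(ddof=0) > 0:
        slope, intercept = np.polyfit(t_std, p_std, 1)
    else:
        slope, intercept = 0.0, 0.0
    fitted = intercept + slope * t_std
    popout_like = np.abs(fitted) - np.abs(p_std)

    order = np.argsort(traits, kind="stable")
    bins = _centile_bins(order, 100)
    centile_of = np.empty(N, dtype=np.int64)
    for c, b in enumerate(bins):
        centile_of[b] = c + 1

    def per_bin(x: np.ndarray, reduce=np.sum) -> np.ndarray:
        return np.array([reduce(x[b]) for b in bins], dtype=float)

    return CentileSummary(
        n_rare_alleles=per_bin(n_rare),
        n_very_rare_alleles=per_bin(n_vrare),
        n_common_alleles=per_bin(n_common),
        n_rare_large_alleles=per_bin(n_rare_large),
        n_very_rare_large_alleles=per_bin(n_vrare_large),
        n_large_effect_rare_carriers=per_bin(carrier_large_rare.astype(float)),
        mean_trait=per_bin(traits, np.mean),
        mean_common_prs=per_bin(p_std, np.mean),
        popout_like_effect=per_bin(popout_like, np.mean),
        centile_of_individual=centile_of,
    )


_ALLELE_CLASSES = {
    "rare": "n_rare_alleles",
    "very_rare": "n_very_rare_alleles",
    "rare_large": "n_rare_large_alleles",
    "very_rare_large": "n_very_rare_large_alleles",
}


def enrichment_log_or(
    selected: Sequence[CentileSummary],
    neutral: Sequence[CentileSummary],
    tail_centiles: Sequence[int],
) -> dict[str, dict[str, float]]:
    """Rare-vs-common tail enrichment of selected over neutral snapshots.

    Per replicate and allele class, the odds ratio
    (rare_sel/common_sel) / (rare_neu/common_neu) is formed from allele
    counts summed over the tail centiles (Haldane 0.5 correction on zero
    cells), and the mean log-OR across replicates is tested against zero
    with a one-sample t-test.
    """
    tail = list(tail_centiles)
    if not tail:
        raise ValueError("tail centile set is empty")
    if len(selected) != len(neutral):
        raise ValueError("selected and neutral collections must pair up")
    idx = np.asarray(tail, dtype=int) - 1
    out: dict[str, dict[str, float]] = {}
    for cls, attr in _ALLELE_CLASSES.items():
        logors = []
        for sel, neu in zip(selected, neutral):
            a = getattr(sel, attr)[idx].sum()
            b = sel.n_common_alleles[idx].sum()
            c = getattr(neu, attr)[idx].sum()
            d = neu.n_common_alleles[idx].sum()
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            logors.append(math.log((a / b) / (c / d)))
        logors = np.asarray(logors)
        if logors.size > 1 and logors.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(logors, 0.0)
        else:
            t, p = (0.0, 1.0) if np.allclose(logors, 0) else (np.inf, 0.0)
        out[cls] = {
            "mean_log_or": float(logors.mean()),
            "t": float(t),
            "p": float(p),
            "n_replicates": int(logors.size),
        }
    return out


def extreme_carrier_fraction(
    pop: SimPopulation,
    config: SimConfig,
    tail_centiles: Sequence[int],
    criterion: str = "removal",
) -> float:
    """Fraction of tail individuals whose extreme value rests on a rare allele.

    ``criterion='removal'``: the individual carries at least one rare
    (MAF < maf_rare) allele whose signed effect points toward the tail and
    whose magnitude is at least the individual's distance from the tail
    threshold — removing it would move them out of the tail.
    ``criterion='large_effect'``: the individual carries a rare allele with
    tail-ward sign in the top ``large_effect_quantile`` of |effect|.
    """
    tail = sorted(tail_centiles)
    if not tail:
        raise ValueError("tail centile set is empty")
    summary = centile_architecture_summary(pop, config)
    centile_of = summary.centile_of_individual
    in_tail = np.isin(centile_of, tail)
    if not in_tail.any():
        return 0.0
    upper = np.mean(tail) > 50
    traits = pop.traits
    # boundary = most extreme trait value just outside the tail set
    outside = ~in_tail
    if outside.any():
        thr = traits[outside].max() if upper else traits[outside].min()
    else:
        thr = traits.min() if upper else traits.max()

    n2, S = pop.genotypes.shape
    if S == 0:
        return 0.0
    freq = pop.counts / n2
    maf = np.minimum(freq, 1.0 - freq)
    rare = maf < config.maf_rare
    toward = pop.effects > 0 if upper else pop.effects < 0
    eligible = rare & toward
    if criterion == "large_effect":
        thr_eff = np.quantile(np.abs(pop.effects), 1.0 - config.large_effect_quantile)
        eligible &= np.abs(pop.effects) >= thr_eff
    elif criterion != "removal":
        raise ValueError("criterion must be 'removal' or 'large_effect'")

    hits = 0
    tail_idx = np.nonzero(in_tail)[0]
    for i in tail_idx:
        carried = pop.genotypes[2 * i] | pop.genotypes[2 * i + 1]
        cand = carried & eligible
        if not cand.any():
            continue
        if criterion == "large_effect":
            hits += 1
            continue
        dist = abs(traits[i] - thr)
        if np.abs(pop.effects[cand]).max() >= dist:
            hits += 1
    return hits / tail_idx.size
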