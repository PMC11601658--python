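"""Synthetic populations, sibling pairs and fecundity data.

These generators produce data with exactly the statistical structure the
tail diagnostics assume, so every pipeline stage can be exercised and
calibrated without biobank access.  The null trait/PRS model is
T = sqrt(r2)*PRS + E with PRS ~ N(0,1) and E ~ N(0, 1-r2); tail enrichment
adds a point-mass rare component (with some carrier probability an
individual receives a fixed signed effect), which is the minimal structure
that produces PRS regression-to-the-mean in a tail.  Sibling pairs follow
the infinitesimal conditional model, optionally overlaid with
family-segregating (Mendelian) or single-sibling (de novo) rare effects.
Fecundity is Poisson with a truncated-linear mean in the trait, the
generative counterpart of the quadratic rLRS regression.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phenotypes import PhenotypeTable
from .sibs import SiblingPairTable

__all__ = ["TailEnrichment", "SynthSpec", "gen_trait_prs", "gen_sibling_pairs", "gen_fecundity"]

#: default birth cohorts for fecundity labels
DEFAULT_COHORTS = ("1934-42", "1943-48", "1949-55", "1956-65")


@dataclass
class TailEnrichment:
    carrier_prob: float = 0.0
    effect: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_prob < 1:
            raise ValueError("carrier_prob must lie in [0, 1)")


@dataclass
class SynthSpec:
    """Parameters of the synthetic generators (see module docstring)."""

    n: int = 100_000
    r2: float = 0.3
    lower: TailEnrichment = field(default_factory=TailEnrichment)
    upper: TailEnrichment = field(default_factory=TailEnrichment)
    h2: float = 0.5
    architecture: str = "polygenic"  # polygenic | mendelian | denovo
    mendelian_effect: float = 3.0
    denovo_effect: float = 3.0
    carrier_prob: float = 0.01
    beta: float = 0.0
    gamma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must lie in (0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.architecture not in ("polygenic", "mendelian", "denovo"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 <= self.carrier_prob < 1:
            raise ValueError("carrier_prob must lie in [0, 1)")


def gen_trait_prs(spec: SynthSpec) -> PhenotypeTable:
    """Standardised trait/PRS population with optional rare tail enrichment.

    Carrier indicators for each tail are kept in ``annotations`` so oracle
    checks can count carriers directly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    prs = rng.standard_normal(n)
    env = rng.normal(0.0, math.sqrt(1.0 - spec.r2), n)
    rare = np.zeros(n)
    ann = {}
    for name, enr in (("lower", spec.lower), ("upper", spec.upper)):
        carrier = rng.random(n) < enr.carrier_prob
        rare += carrier * enr.effect
        ann[f"carrier_{name}"] = carrier
        if enr.carrier_prob * abs(enr.effect) > 0.5:
            _warnings.warn(
                f"{name} tail enrichment (p={enr.carrier_prob}, effect={enr.effect}) "
                "shifts the trait mean enough to strain the standardisation"
            )
    trait = math.sqrt(spec.r2) * prs + rare + env

    def std(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=0)

    return PhenotypeTable(
        individual_id=np.arange(n),
        trait=std(trait),
        prs=std(prs),
        annotations=ann,
    )


def gen_sibling_pairs(spec: SynthSpec) -> SiblingPairTable:
    """Sibling pairs under polygenic, Mendelian or de novo architecture.

    Polygenic: per-sib genetic values share a N(0, h2/2) component (so the
    sib covariance is h2/2 and each genetic variance h2) plus independent
    N(0, 1-h2) environments — the generative counterpart of the conditional
    model N(s1*h2/2, 1-h2^2/4).  Mendelian: with probability
    ``carrier_prob`` a parent carries an allele of effect
    ``mendelian_effect`` transmitted independently to each sibling with
    probability 1/2.  De novo: with probability ``carrier_prob`` sibling 1
    alone receives ``denovo_effect``.  Outputs are standardised jointly;
    carrier/transmission annotations are attached to the table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    h2 = spec.h2
    shared = rng.normal(0.0, math.sqrt(h2 / 2.0), n)
    g1 = shared + rng.normal(0.0, math.sqrt(h2 / 2.0), n)
    g2 = shared + rng.normal(0.0, math.sqrt(h2 / 2.0), n)
    e_sd = math.sqrt(1.0 - h2)
    s1 = g1 + rng.normal(0.0, e_sd, n)
    s2 = g2 + rng.normal(0.0, e_sd, n)

    ann: dict[str, np.ndarray] = {}
    if spec.architecture == "mendelian":
        parent_carrier = rng.random(n) < spec.carrier_prob
        t1 = parent_carrier & (rng.random(n) < 0.5)
        t2 = parent_carrier & (rng.random(n) < 0.5)
        s1 = s1 + t1 * spec.mendelian_effect
        s2 = s2 + t2 * spec.mendelian_effect
        ann = {"parent_carrier": parent_carrier, "transmitted_s1": t1, "transmitted_s2": t2}
    elif spec.architecture == "denovo":
        carrier = rng.random(n) < spec.carrier_prob
        s1 = s1 + carrier * spec.denovo_effect
        ann = {"denovo_s1": carrier}

    pooled = np.concatenate([s1, s2])
    mu, sd = pooled.mean(), pooled.std(ddof=0)
    return SiblingPairTable(
        pair_id=np.arange(n), s1=(s1 - mu) / sd, s2=(s2 - mu) / sd, annotations=ann
    )


def gen_fecundity(
    trait: np.ndarray,
    beta: float,
    gamma: float,
    seed: int = 0,
    baseline_mean: float = 2.0,
    cohorts: tuple = DEFAULT_COHORTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Offspring counts with a truncated-linear Poisson link in the trait.

    Expected count lambda(z) = max(eps, c * (1 + beta*z + gamma*z^2)) with
    baseline c (default 2 offspring); counts are Poisson, cohort labels are
    assigned round-robin.  For small |beta|, |gamma| the linear rLRS
    regression recovers the generating coefficients.
    """
    trait = np.asarray(trait, dtype=float)
    rng = np.random.default_rng(seed)
    lam = baseline_mean * (1.0 + beta * trait + gamma * trait * trait)
    lam = np.maximum(1e-9, lam)
    counts = rng.poisson(lam)
    labels = np.asarray(cohorts)[np.arange(trait.size) % len(cohorts)]
    return counts, labels
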