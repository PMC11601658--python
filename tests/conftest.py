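import numpy as np
import pytest

from popout import PhenotypeTable, SynthSpec, TailEnrichment, gen_trait_prs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bivariate_table():
    """Null table: trait and PRS bivariate normal with correlation 0.5."""
    rng = np.random.default_rng(7)
    n = 100_000
    prs = rng.standard_normal(n)
    trait = 0.5 * prs + np.sqrt(0.75) * rng.standard_normal(n)
    return PhenotypeTable(individual_id=np.arange(n), trait=trait, prs=prs)


@pytest.fixture
def enriched_table():
    """Upper-tail rare enrichment: carriers (p=0.01) get +3 on the trait."""
    spec = SynthSpec(
        n=100_000, r2=0.3, upper=TailEnrichment(carrier_prob=0.01, effect=3.0), seed=42
    )
    return gen_trait_prs(spec)
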