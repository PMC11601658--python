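"""Detect rare-allele tail architecture with the POPout test.

Builds a synthetic population of 100,000 individuals whose upper trait tail
is enriched for carriers of a rare large-effect allele (carrier probability
1%, effect +3 SD), runs the tail test, and prints the per-tail effects.  A
positive effect means the observed PRS of tail individuals regresses toward
the population mean relative to the linear PRS-on-trait prediction — the
signature of rare variants missing from the score.
"""

import numpy as np

from popout import SynthSpec, TailEnrichment, bh_fdr, gen_trait_prs, popout_test

table = gen_trait_prs(
    SynthSpec(n=100_000, r2=0.3, upper=TailEnrichment(carrier_prob=0.01, effect=3.0), seed=7)
)
result = popout_test(table, tail_fraction=0.01)
q = bh_fdr([result.lower.p_value, result.upper.p_value])

print(f"regression: PRS = {result.intercept:+.4f} {result.slope:+.4f} * trait")
for tail, qv in zip(result.tails, q):
    print(
        f"{tail.tail:>5} tail: n={tail.n}  effect={tail.effect:+.3f}  "
        f"t={tail.t_statistic:+.2f}  p={tail.p_value:.2e}  q={qv:.2e}"
    )
print(f"middle-centile QC pass: {result.qc_pass}")
print(
    "\nThe enriched upper tail shows a clearly positive effect (PRS pulled back\n"
    "toward the mean by the un-scored rare allele); the lower tail shows only\n"
    "the small negative spillover from the carriers' tilt of the global fit."
)
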