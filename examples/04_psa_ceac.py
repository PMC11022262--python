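"""Probabilistic sensitivity analysis and the acceptability curve.

Draws every uncertain parameter from its distribution 2,000 times
(Beta for probabilities/utilities, Gamma for costs, log-Normal for
ratios), runs both strategies per draw, and summarises the incremental
cloud on the cost-effectiveness plane and the CEAC.
"""

import numpy as np

from eipcea import default_inputs
from eipcea.economics import (
    ModelContext,
    ceac,
    default_lambda_grid,
    quadrant_fractions,
    run_psa,
)

table, life, *_ = default_inputs()
ctx = ModelContext(life_table=life)

psa = run_psa(table, ctx, n_draws=2_000, seed=7)

print(f"{psa.n_draws} draws: mean ΔC = R$ {np.mean(psa.delta_cost):,.0f}, "
      f"mean ΔE = {np.mean(psa.delta_qalys):.3f} QALYs")
print(f"mean of per-draw ICERs: R$ {psa.mean_icer_of_ratios():,.0f}; "
      f"ratio of means: R$ {psa.icer_of_means():,.0f}")
quads = quadrant_fractions(psa)
print("cost-effectiveness plane quadrants:",
      {k: f"{100 * v:.1f}%" for k, v in quads.items()})

curve = ceac(psa, default_lambda_grid(18_254.0))
for lam in (18_254.0, 54_762.0):
    print(f"P(EIP cost-effective at λ = R$ {lam:,.0f}) = {100 * curve.at(lam):.1f}%")
# NE = more effective but costlier, SE = more effective and cheaper
# (dominant).  The CEAC gives the probability that the incremental net
# monetary benefit is positive at each willingness-to-pay threshold.
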