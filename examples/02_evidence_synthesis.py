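"""Pool trial and cohort evidence with the power prior at several weights.

Fits the hierarchical random-effects meta-analysis of the remission
trials alone (weight 0), then adds the single-arm cohort likelihood at
weights 0.5 and 1.  At full weight the credible interval tightens
somewhat while the mean moves only modestly — the cohort enters as one
extra (imprecise, single-arm) study, so it cannot dominate the pooled
estimate.
"""

from eipcea import SynthesisConfig, alpha_sweep, default_inputs
from eipcea.synthesis import summaries_to_frame

table, life, trials_rem, trials_rel, ipd = default_inputs()

# reduced sampler settings keep this demo around half a minute
config = SynthesisConfig(outcome="remission", iterations=20_000, burn_in=4_000, seed=42)
summaries = alpha_sweep(trials_rem, ipd, [0.0, 0.5, 1.0], config)

print(summaries_to_frame(summaries).round(3).to_string(index=False))
for s in summaries:
    print(f"alpha={s.alpha:.1f}: pooled remission RR {s.rr_mean:.2f} "
          f"(95% CrI {s.cri_low:.2f}-{s.cri_high:.2f}), "
          f"R-hat {s.rhat_max:.3f}")
# An RR above 1 favours early intervention: e.g. 1.45 means a 45% higher
# probability of 12-month remission than under community care.
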