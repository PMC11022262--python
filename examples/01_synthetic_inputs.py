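"""Generate the synthetic study inputs and look at what they contain.

Builds the frozen default bundle — parameter table, life table, seven
two-arm trials per outcome, and a 357-person IPD cohort — and prints the
headline descriptive figures (cohort profile, trial scale, crude pooled
risk ratios).
"""

from eipcea import default_inputs

table, life, trials_rem, trials_rel, ipd = default_inputs()

print(f"cohort: n={len(ipd)}, {100 * (ipd.sex == 'M').mean():.0f}% male, "
      f"mean (SD) age {ipd.age.mean():.1f} ({ipd.age.std():.2f})")
print(f"12-month outcomes: remission {ipd.remission_12m.mean():.3f}, "
      f"relapse {ipd.relapse_12m.mean():.3f}")

for name, trials in (("remission", trials_rem), ("relapse", trials_rel)):
    n_total = int(trials[["n_t", "n_c"]].sum().sum())
    crude = (trials.events_t.sum() / trials.n_t.sum()) / (
        trials.events_c.sum() / trials.n_c.sum()
    )
    print(f"{name} trials: k={len(trials)}, {n_total} participants, "
          f"crude pooled RR {crude:.2f}")

print(f"life table: ages {life.ages[0]}-{life.ages[-1]}, "
      f"q(26)={life.prob(26):.4f}, q(80)={life.prob(80):.3f}")
print(f"parameter table: {len(table)} rows; FEP→remission (comparator) "
      f"= {table['p_fep_remission']:.2f}, SMR = {table['smr']:.1f}")
# The crude pooled RRs sit near the published aggregate estimates (1.41
# for remission, 0.66 for relapse); the cohort emulates the São Paulo
# first-episode-psychosis cohort profile.
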