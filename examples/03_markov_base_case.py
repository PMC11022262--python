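"""Run the six-state Markov cohort model and compute the base-case ICER.

Uses the parameter table's point estimates (including the pooled risk
ratios) to trace a cohort entering at first-episode psychosis through
10 annual cycles under each strategy, then compares discounted costs
and QALYs.
"""

from eipcea import default_inputs, remission_at_1yr
from eipcea.economics import ModelContext, convert_currency, icer_per_remission, run_base_case

table, life, *_ = default_inputs()
ctx = ModelContext(life_table=life, horizon=10, discount_rate=0.03, start_age=26)

cea, res_eip, res_caps = run_base_case(table, ctx, thresholds=[18_254.0, 54_762.0])

print(res_eip.trace.to_frame().round(3).head(4).to_string(index=False))
print(f"remission at 1 year: EIP {100 * remission_at_1yr(res_eip.trace):.1f}% "
      f"vs CAPS {100 * remission_at_1yr(res_caps.trace):.1f}%")
print(f"discounted totals per patient — EIP: R$ {cea.cost_eip:,.0f} / "
      f"{cea.qalys_eip:.3f} QALYs; CAPS: R$ {cea.cost_caps:,.0f} / "
      f"{cea.qalys_caps:.3f} QALYs")
print(f"incremental: ΔC = R$ {cea.delta_cost:,.0f}, ΔE = {cea.delta_qalys:.3f} QALYs")
print(f"ICER = R$ {cea.icer:,.0f} (USD {convert_currency(cea.icer):,.0f} PPP) per QALY")
for lam, inmb in cea.nmb_at.items():
    verdict = "cost-effective" if inmb > 0 else "not cost-effective"
    print(f"  at λ = R$ {lam:,.0f}/QALY: incremental NMB = R$ {inmb:,.0f} ({verdict})")
value, label = icer_per_remission(res_eip, res_caps, ctx.discount_rate)
print(f"cost per additional 1-year remission: R$ {value:,.0f} {label}")
# An ICER below the willingness-to-pay threshold (1 GDP per capita,
# R$ 18,254/QALY) means the extra cost per QALY gained is considered
# acceptable to the health system.
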