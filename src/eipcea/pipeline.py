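"""End-to-end pipeline: synthesis -> Markov model -> CEA -> PSA -> scenarios.

``run_pipeline`` ties the stages together from a :class:`~eipcea.io.RunConfig`,
writes every result table to ``config.out_dir`` (CSV/JSON only) together
with a provenance block (config hash, seed, package versions), and returns
the in-memory bundle.  Given the same config and seed, two runs produce
identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .economics import (
    CurrencyConfig,
    ModelContext,
    ceac,
    compute_icer,
    convert_currency,
    default_lambda_grid,
    icer_per_remission,
    quadrant_fractions,
    run_base_case,
    run_psa,
    run_scenarios,
)
from .io import (
    RunConfig,
    load_ipd_csv,
    load_life_table_csv,
    load_parameters,
    load_trials_csv,
    validate_config,
)
from .markov import remission_at_1yr
from .synthesis import SynthesisConfig, alpha_sweep, summaries_to_frame
from .synthetic import default_inputs

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_inputs"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds (< 2^31) derived from one master seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


def load_inputs(config: RunConfig):
    """Load the configured input files, falling back to the frozen
    synthetic study bundle (the run seed drives only the analysis)."""
    table, life, trials_rem, trials_rel, ipd = default_inputs()
    if config.parameters_csv:
        table = load_parameters(config.parameters_csv)
    if config.life_table_csv:
        life = load_life_table_csv(config.life_table_csv)
    if config.trials_remission_csv:
        trials_rem = load_trials_csv(config.trials_remission_csv)
    if config.trials_relapse_csv:
        trials_rel = load_trials_csv(config.trials_relapse_csv)
    if config.ipd_csv:
        ipd = load_ipd_csv(config.ipd_csv)
    return table, life, trials_rem, trials_rel, ipd


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run every analysis stage and (optionally) write the result bundle."""
    table, life, trials_rem, trials_rel, ipd = load_inputs(config)
    validate_config(config, life_table=life)
    seeds = _child_seeds(config.seed, 4)

    # --- evidence synthesis (both outcomes, weight sweep incl. config.alpha)
    alphas = sorted({0.0, 0.5, 1.0, config.alpha})
    summaries = {}
    for outcome, trials, seed in (
        ("remission", trials_rem, seeds[0]),
        ("relapse", trials_rel, seeds[1]),
    ):
        cfg = SynthesisConfig(
            outcome=outcome,
            chains=config.chains,
            iterations=config.iterations,
            burn_in=config.burn_in,
            seed=seed,
        )
        summaries[outcome] = alpha_sweep(trials, ipd, alphas, cfg)
    evidence = pd.concat(
        [summaries_to_frame(s) for s in summaries.values()], ignore_index=True
    )

    def _at_alpha(outcome):
        return next(s for s in summaries[outcome] if s.alpha == config.alpha)

    rr_rem = _at_alpha("remission")
    rr_rel = _at_alpha("relapse")
    logger.info(
        "pooled RRs at alpha=%.2f: remission %.3f (%.3f-%.3f), relapse %.3f (%.3f-%.3f)",
        config.alpha, rr_rem.rr_mean, rr_rem.cri_low, rr_rem.cri_high,
        rr_rel.rr_mean, rr_rel.cri_low, rr_rel.cri_high,
    )

    # --- base case with synthesis point estimates plugged into the table
    table_cea = table.replace_values(
        {"rr_remission": rr_rem.rr_mean, "rr_relapse": rr_rel.rr_mean}
    )
    ctx = ModelContext(
        life_table=life,
        horizon=config.horizon,
        discount_rate=config.discount_rate,
        start_age=config.start_age,
    )
    cea, res_eip, res_caps = run_base_case(table_cea, ctx, config.thresholds)
    rem_icer, rem_label = icer_per_remission(res_eip, res_caps, config.discount_rate)

    # --- PSA propagating the posterior RR draws
    psa = run_psa(
        table_cea,
        ctx,
        n_draws=config.psa_draws,
        seed=seeds[2],
        rr_draws={
            "rr_remission": rr_rem.draws["rr"],
            "rr_relapse": rr_rel.draws["rr"],
        },
    )
    quadrants = quadrant_fractions(psa)
    curve = ceac(psa, default_lambda_grid(config.gdp_pc))
    prob_ce = {lam: float(np.mean(lam * psa.delta_qalys - psa.delta_cost > 0)) for lam in config.thresholds}

    # --- deterministic scenarios
    scen = run_scenarios(table_cea, ctx, config.scenarios, config.thresholds)

    fx = CurrencyConfig()
    bundle = {
        "evidence": evidence,
        "summaries": summaries,
        "base_case": cea,
        "result_eip": res_eip,
        "result_caps": res_caps,
        "remission_at_1yr_eip": remission_at_1yr(res_eip.trace),
        "remission_at_1yr_caps": remission_at_1yr(res_caps.trace),
        "icer_per_remission": rem_icer,
        "icer_per_remission_label": rem_label,
        "psa": psa,
        "quadrants": quadrants,
        "ceac": curve,
        "prob_cost_effective": prob_ce,
        "scenarios": scen,
        "icer_usd_ppp": convert_currency(cea.icer, fx) if np.isfinite(cea.icer) else None,
    }
    if write:
        _write_bundle(config, bundle)
    return bundle


def _write_bundle(config: RunConfig, bundle: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle["evidence"].to_csv(out / "evidence.csv", index=False)
    bundle["result_eip"].trace.to_csv(out / "trace_eip.csv")
    bundle["result_caps"].trace.to_csv(out / "trace_caps.csv")
    bundle["ceac"].to_frame().to_csv(out / "ceac.csv", index=False)
    bundle["scenarios"].to_csv(out / "scenarios.csv", index=False)

    cea = bundle["base_case"]
    base = cea.to_dict()
    base["remission_at_1yr_eip"] = bundle["remission_at_1yr_eip"]
    base["remission_at_1yr_caps"] = bundle["remission_at_1yr_caps"]
    base["icer_per_remission"] = (
        None if not np.isfinite(bundle["icer_per_remission"]) else bundle["icer_per_remission"]
    )
    base["icer_usd_ppp"] = bundle["icer_usd_ppp"]
    with open(out / "base_case.json", "w") as fh:
        json.dump(base, fh, indent=2)

    psa = bundle["psa"]
    psa_summary = {
        "n_draws": psa.n_draws,
        "seed": psa.seed,
        "mean_delta_cost": float(np.mean(psa.delta_cost)),
        "mean_delta_qalys": float(np.mean(psa.delta_qalys)),
        "mean_icer_of_ratios": psa.mean_icer_of_ratios(),
        "icer_of_means": psa.icer_of_means(),
        "quadrants": bundle["quadrants"],
        "prob_cost_effective": {f"{k:g}": v for k, v in bundle["prob_cost_effective"].items()},
    }
    with open(out / "psa_summary.json", "w") as fh:
        json.dump(psa_summary, fh, indent=2)

    import emcee
    import scipy

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "versions": {
            "eipcea": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "emcee": emcee.__version__,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
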