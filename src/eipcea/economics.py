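"""Decision analysis: ICER, net monetary benefit, PSA, CEAC, scenarios.

Incremental quantities are always EIP minus CAPS.  The cost-effectiveness
plane convention: x = incremental QALYs (ΔE), y = incremental cost (ΔC);
the southeast quadrant (ΔE > 0, ΔC < 0) is dominance of EIP.  Monetary
amounts are R$; :func:`convert_currency` divides by a purchasing-power-
parity factor for USD reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ParameterTable
from .markov import (
    CohortResult,
    LifeTable,
    StateValues,
    StrategySpec,
    TransitionParameters,
    remission_at_1yr,
    run_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "CurrencyConfig",
    "CEAResult",
    "PSASamples",
    "CEACCurve",
    "ModelContext",
    "compute_icer",
    "compute_nmb",
    "incremental_nmb",
    "run_base_case",
    "run_psa",
    "quadrant_fractions",
    "ceac",
    "default_lambda_grid",
    "run_scenarios",
    "SCENARIOS",
    "convert_currency",
    "icer_per_remission",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Willingness-to-pay thresholds anchored at GDP per capita (R$/QALY)."""

    gdp_pc: float = 18_254.0
    multipliers: tuple[float, ...] = (1.0, 3.0)

    def __post_init__(self):
        if self.gdp_pc <= 0 or any(m <= 0 for m in self.multipliers):
            raise ValueError("thresholds must be positive")

    @property
    def lambdas(self) -> list[float]:
        return [m * self.gdp_pc for m in self.multipliers]


@dataclass(frozen=True)
class CurrencyConfig:
    """R$ per PPP-adjusted USD.  Default back-derived from the study's
    printed pair R$ 15,495 <-> USD 7,640."""

    ppp_factor: float = 15_495.0 / 7_640.0

    def __post_init__(self):
        if self.ppp_factor <= 0:
            raise ValueError("ppp_factor must be positive")


def convert_currency(amount_brl: float, config: CurrencyConfig = CurrencyConfig()) -> float:
    """Convert R$ to PPP-adjusted USD."""
    return amount_brl / config.ppp_factor


def compute_nmb(lam: float, qalys: float, cost: float) -> float:
    """Net monetary benefit ``lambda * E - C`` at willingness-to-pay ``lam``."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * qalys - cost


def incremental_nmb(lam: float, delta_qalys: float, delta_cost: float) -> float:
    """Incremental NMB ``lambda * dE - dC``; positive favours EIP."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * delta_qalys - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Base-case cost-effectiveness comparison (deltas are EIP minus CAPS)."""

    cost_caps: float
    qalys_caps: float
    cost_eip: float
    qalys_eip: float
    delta_cost: float
    delta_qalys: float
    icer: float  # NaN when labelled
    icer_label: str  # "", "EIP dominant", "EIP dominated", "undefined"
    nmb_at: Mapping[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "cost_caps": self.cost_caps,
            "qalys_caps": self.qalys_caps,
            "cost_eip": self.cost_eip,
            "qalys_eip": self.qalys_eip,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": None if np.isnan(self.icer) else self.icer,
            "icer_label": self.icer_label,
            "incremental_nmb": {f"{k:g}": v for k, v in self.nmb_at.items()},
        }
        return out


def compute_icer(
    cost_caps: float,
    qalys_caps: float,
    cost_eip: float,
    qalys_eip: float,
    thresholds: Sequence[float] = (),
) -> CEAResult:
    """ICER = ΔC/ΔE with dominance labelling; never divides by ΔE = 0.

    ``nmb_at`` maps each threshold to the incremental NMB.
    """
    d_c = cost_eip - cost_caps
    d_e = qalys_eip - qalys_caps
    icer, label = np.nan, ""
    if d_e == 0.0:
        label = "undefined"
    elif d_c < 0 and d_e > 0:
        label = "EIP dominant"
        icer = d_c / d_e  # negative ratio still reported alongside the label
    elif d_c > 0 and d_e < 0:
        label = "EIP dominated"
        icer = d_c / d_e
    else:
        icer = d_c / d_e
    nmb = {lam: incremental_nmb(lam, d_e, d_c) for lam in thresholds}
    return CEAResult(
        cost_caps=cost_caps,
        qalys_caps=qalys_caps,
        cost_eip=cost_eip,
        qalys_eip=qalys_eip,
        delta_cost=d_c,
        delta_qalys=d_e,
        icer=icer,
        icer_label=label,
        nmb_at=nmb,
    )


@dataclass(frozen=True)
class ModelContext:
    """Everything the Markov engine needs besides the parameter values."""

    life_table: LifeTable
    horizon: int = 10
    discount_rate: float = 0.03
    start_age: int = 26
    eip: StrategySpec = StrategySpec("EIP")
    caps: StrategySpec = StrategySpec("CAPS")
    half_cycle: bool = False

    def run_strategy(
        self, params: TransitionParameters, values: StateValues, strategy: StrategySpec
    ) -> CohortResult:
        return run_cohort(
            params,
            values,
            strategy,
            self.life_table,
            horizon=self.horizon,
            discount_rate=self.discount_rate,
            start_age=self.start_age,
            half_cycle=self.half_cycle,
        )

    def run_both(self, params, values) -> tuple[CohortResult, CohortResult]:
        return (
            self.run_strategy(params, values, self.eip),
            self.run_strategy(params, values, self.caps),
        )


def run_base_case(
    table: ParameterTable, ctx: ModelContext, thresholds: Sequence[float] = ()
) -> tuple[CEAResult, CohortResult, CohortResult]:
    """Deterministic comparison at the table's point estimates."""
    params = TransitionParameters.from_table(table)
    values = StateValues.from_table(table)
    res_eip, res_caps = ctx.run_both(params, values)
    cea = compute_icer(
        res_caps.discounted_cost,
        res_caps.discounted_qalys,
        res_eip.discounted_cost,
        res_eip.discounted_qalys,
        thresholds,
    )
    return cea, res_eip, res_caps


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_MAX_RESAMPLE = 100


@dataclass
class PSASamples:
    """Joint parameter draws with per-strategy (cost, QALY) results."""

    parameters: pd.DataFrame  # one row per draw
    cost_eip: np.ndarray
    qalys_eip: np.ndarray
    cost_caps: np.ndarray
    qalys_caps: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.cost_eip)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_eip - self.cost_caps

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys_eip - self.qalys_caps

    def icers(self) -> np.ndarray:
        """Per-draw ΔC/ΔE; NaN where ΔE = 0."""
        d_e = self.delta_qalys
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(d_e != 0.0, self.delta_cost / d_e, np.nan)
        return out

    def mean_icer_of_ratios(self) -> float:
        """Mean of per-draw ICERs (NaN draws excluded)."""
        return float(np.nanmean(self.icers()))

    def icer_of_means(self) -> float:
        """Ratio of mean ΔC over mean ΔE."""
        return float(np.mean(self.delta_cost) / np.mean(self.delta_qalys))


def run_psa(
    table: ParameterTable,
    ctx: ModelContext,
    n_draws: int = 5_000,
    seed: int = 0,
    rr_draws: Mapping[str, np.ndarray] | None = None,
) -> PSASamples:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Each draw samples every parameter from its table distribution
    (independently across rows), runs both strategies on the shared draw,
    and records discounted totals.  ``rr_draws`` may supply posterior
    samples for ``rr_remission``/``rr_relapse`` from the evidence
    synthesis; those parameters are then resampled from the posterior
    instead of the table's distribution, propagating the synthesis
    uncertainty without refitting.  Draws whose transition probabilities
    are jointly inconsistent (negative residual stay-probability) are
    rejected and resampled, up to 100 attempts each.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[dict[str, float]] = []
    cost_e = np.empty(n_draws)
    qaly_e = np.empty(n_draws)
    cost_c = np.empty(n_draws)
    qaly_c = np.empty(n_draws)
    for i in range(n_draws):
        for attempt in range(_MAX_RESAMPLE):
            draw = table.sample(rng)
            if rr_draws:
                for name, pool in rr_draws.items():
                    draw[name] = float(pool[rng.integers(len(pool))])
            try:
                params = TransitionParameters(
                    p_fep_remission=draw["p_fep_remission"],
                    p_fep_trs=draw["p_fep_trs"],
                    p_fep_pns=draw["p_fep_pns"],
                    p_remission_relapse=draw["p_remission_relapse"],
                    p_relapse_remission=draw["p_relapse_remission"],
                    p_relapse_trs=draw["p_relapse_trs"],
                    p_relapse_inpatient=draw["p_relapse_inpatient"],
                    rr_remission=draw["rr_remission"],
                    rr_relapse=draw["rr_relapse"],
                    smr=draw["smr"],
                )
                values = StateValues(
                    annual_costs=np.array(
                        [draw["c_fep"], draw["c_remission"], draw["c_relapse"],
                         draw["c_trs"], draw["c_pns"], 0.0]
                    ),
                    utilities=np.array(
                        [draw["u_fep"], draw["u_remission"], draw["u_relapse"],
                         draw["u_trs"], draw["u_pns"], 0.0]
                    ),
                    inpatient_episode_cost=draw["c_inpatient_episode"],
                    eip_program_annual_cost=draw["c_eip_program"],
                )
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"draw {i}: no valid parameter vector after {_MAX_RESAMPLE} attempts"
            )
        res_e, res_c = ctx.run_both(params, values)
        cost_e[i], qaly_e[i] = res_e.discounted_cost, res_e.discounted_qalys
        cost_c[i], qaly_c[i] = res_c.discounted_cost, res_c.discounted_qalys
        records.append(draw)
    return PSASamples(
        parameters=pd.DataFrame.from_records(records),
        cost_eip=cost_e,
        qalys_eip=qaly_e,
        cost_caps=cost_c,
        qalys_caps=qaly_c,
        seed=seed,
    )


def quadrant_fractions(samples: PSASamples) -> dict[str, float]:
    """Fractions of PSA draws per cost-effectiveness-plane quadrant.

    Exact zeros in ΔE or ΔC are assigned to the positive side (and
    logged); the four fractions sum to 1 exactly.
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one PSA draw")
    d_e, d_c = samples.delta_qalys, samples.delta_cost
    n_ties = int(np.sum(d_e == 0.0) + np.sum(d_c == 0.0))
    if n_ties:
        logger.info("%d exact zeros in PSA deltas assigned to the positive side", n_ties)
    e_pos = d_e >= 0.0
    c_pos = d_c >= 0.0
    n = samples.n_draws
    return {
        "NE": float(np.sum(e_pos & c_pos)) / n,
        "SE": float(np.sum(e_pos & ~c_pos)) / n,
        "SW": float(np.sum(~e_pos & ~c_pos)) / n,
        "NW": float(np.sum(~e_pos & c_pos)) / n,
    }


@dataclass(frozen=True)
class CEACCurve:
    """Probability of EIP being cost-effective along a willingness grid."""

    lam: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lam, "probability": self.probability})

    def at(self, lam: float) -> float:
        i = int(np.argmin(np.abs(self.lam - lam)))
        return float(self.probability[i])


def default_lambda_grid(gdp_pc: float = 18_254.0, n: int = 100) -> np.ndarray:
    """0 to 3x GDP per capita in ``n`` steps."""
    return np.linspace(0.0, 3.0 * gdp_pc, n)


def ceac(samples: PSASamples, lam_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve.

    At each threshold, the probability is the fraction of draws with
    strictly positive incremental NMB; at lambda = 0 this is the fraction
    of cost-saving draws, and for large lambda it tends to the fraction
    with positive incremental QALYs.
    """
    lam = np.asarray(list(lam_grid), dtype=float)
    if lam.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(np.diff(lam) <= 0) and lam.size > 1:
        raise ValueError("lambda grid must be strictly increasing")
    inmb = lam[:, None] * samples.delta_qalys[None, :] - samples.delta_cost[None, :]
    prob = np.mean(inmb > 0.0, axis=1)
    return CEACCurve(lam=lam, probability=prob)


# ---------------------------------------------------------------------------
# deterministic scenario analyses
# ---------------------------------------------------------------------------

#: scenario name -> (description, context/strategy overrides)
SCENARIOS = {
    "base": "10-year horizon, 3-year EIP package",
    "horizon_20": "20-year horizon",
    "horizon_30": "30-year horizon",
    "lifetime_75": "lifetime horizon (75 years)",
    "eip_5yr": "EIP effectiveness and costs last 5 years",
    "mortality_effect": "EIP also reduces mortality (risk ratio on SMR)",
}


def _scenario_context(name: str, ctx: ModelContext, mortality_rr: float) -> ModelContext:
    import dataclasses

    if name == "base":
        return ctx
    if name == "horizon_20":
        return dataclasses.replace(ctx, horizon=20)
    if name == "horizon_30":
        return dataclasses.replace(ctx, horizon=30)
    if name == "lifetime_75":
        return dataclasses.replace(ctx, horizon=75)
    if name == "eip_5yr":
        eip = dataclasses.replace(ctx.eip, effect_duration=5, cost_duration=5)
        return dataclasses.replace(ctx, eip=eip)
    if name == "mortality_effect":
        eip = dataclasses.replace(ctx.eip, mortality_rr=mortality_rr)
        return dataclasses.replace(ctx, eip=eip)
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
    )


def run_scenarios(
    table: ParameterTable,
    ctx: ModelContext,
    names: Sequence[str] = tuple(SCENARIOS),
    thresholds: Sequence[float] = (),
    mortality_rr: float = 0.7,
) -> pd.DataFrame:
    """One deterministic CEA row per scenario.

    ``mortality_rr`` is the exploratory risk ratio applied to the SMR under
    EIP in the mortality-effect scenario (survival benefit of early
    intervention); the base case leaves mortality untouched.
    """
    rows = []
    for name in names:
        sctx = _scenario_context(name, ctx, mortality_rr)
        cea, _, _ = run_base_case(table, sctx, thresholds)
        rows.append(
            {
                "scenario": name,
                "description": SCENARIOS[name],
                "horizon": sctx.horizon,
                "cost_caps": cea.cost_caps,
                "qalys_caps": cea.qalys_caps,
                "cost_eip": cea.cost_eip,
                "qalys_eip": cea.qalys_eip,
                "delta_cost": cea.delta_cost,
                "delta_qalys": cea.delta_qalys,
                "icer": cea.icer,
                "icer_label": cea.icer_label,
            }
        )
    return pd.DataFrame(rows)


def icer_per_remission(
    res_eip: CohortResult, res_caps: CohortResult, discount_rate: float = 0.03
) -> tuple[float, str]:
    """Cost per additional remission at 1 year.

    ΔC is the discounted first-cycle cost difference; the denominator is
    the difference in REMISSION occupancy at cycle 1.  Returns
    ``(value, label)``; a zero remission difference yields ``(nan,
    "undefined")``.
    """
    disc = (1.0 + discount_rate) ** -1
    d_cost = (res_eip.cycle_costs[1] - res_caps.cycle_costs[1]) * disc
    d_rem = remission_at_1yr(res_eip.trace) - remission_at_1yr(res_caps.trace)
    if d_rem == 0.0:
        return float("nan"), "undefined"
    return d_cost / d_rem, ""
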