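"""Six-state cohort Markov model of early psychosis.

The cohort enters at first-episode psychosis (FEP) and moves annually
between six mutually exclusive health states::

    FEP -> REMISSION | TRS | PNS (or stays in FEP)
    REMISSION <-> RELAPSE
    RELAPSE -> TRS
    every alive state -> DEATH

TRS (treatment-resistant schizophrenia) and PNS (persistent negative
symptoms) are chronic: their only exit is death.  Background mortality is
an age-specific life-table probability inflated by the standardised
mortality ratio (SMR) of psychotic illness; it is applied first each
cycle, and the remaining probability mass is split according to the
conditional clinical transition probabilities.

Under the EIP strategy, remission-type probabilities (FEP→REMISSION,
RELAPSE→REMISSION) are multiplied by the pooled remission risk ratio and
the relapse probability (REMISSION→RELAPSE) by the relapse risk ratio,
for the duration of the care package; afterwards EIP reverts to the
comparator (CAPS) dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HealthState",
    "N_STATES",
    "TransitionParameters",
    "StateValues",
    "StrategySpec",
    "LifeTable",
    "CohortTrace",
    "CohortResult",
    "combine_mortality",
    "build_transition_matrix",
    "run_cohort",
    "remission_at_1yr",
]


class HealthState(IntEnum):
    """The model's six mutually exclusive health states (DEATH absorbing)."""

    FEP = 0
    REMISSION = 1
    RELAPSE = 2
    TRS = 3
    PNS = 4
    DEATH = 5


N_STATES = len(HealthState)


def combine_mortality(q: float, smr: float) -> float:
    """Combine a general-population annual death probability with an SMR.

    The probability is converted to a rate, scaled, and converted back:
    ``1 - (1 - q)**smr``, which equals ``1 - exp(smr * ln(1 - q))``.
    Result stays in ``[0, 1)`` for ``q in [0, 1)`` and ``smr > 0``.
    """
    q = float(q)
    if not 0.0 <= q < 1.0:
        raise ValueError(f"annual death probability q={q} must lie in [0, 1)")
    if smr <= 0:
        raise ValueError(f"smr={smr} must be positive")
    return 1.0 - (1.0 - q) ** smr


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities q(age)."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.shape != q.shape or ages.ndim != 1:
            raise ValueError("ages and q must be matching 1-D arrays")
        if len(ages) == 0:
            raise ValueError("life table is empty")
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("life-table q values must lie in [0, 1)")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be consecutive integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    def prob(self, age: int) -> float:
        """Annual death probability at integer ``age``."""
        i = int(age) - int(self.ages[0])
        if i < 0 or i >= len(self.q):
            raise ValueError(
                f"life table covers ages {self.ages[0]}–{self.ages[-1]}, "
                f"requested {age}"
            )
        return float(self.q[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TransitionParameters:
    """Baseline (CAPS) annual transition probabilities plus treatment effects.

    The six clinical edges are conditional on surviving the cycle; each
    state's outgoing probabilities must leave a non-negative residual
    stay-probability.  ``rr_remission``/``rr_relapse`` are the pooled risk
    ratios applied under EIP; ``smr`` multiplies background mortality in
    every alive state.
    """

    p_fep_remission: float
    p_fep_trs: float
    p_fep_pns: float
    p_remission_relapse: float
    p_relapse_remission: float
    p_relapse_trs: float
    p_relapse_inpatient: float
    rr_remission: float = 1.0
    rr_relapse: float = 1.0
    smr: float = 1.0

    def __post_init__(self):
        for name in (
            "p_fep_remission",
            "p_fep_trs",
            "p_fep_pns",
            "p_remission_relapse",
            "p_relapse_remission",
            "p_relapse_trs",
            "p_relapse_inpatient",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("rr_remission", "rr_relapse", "smr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fep_out = self.p_fep_remission + self.p_fep_trs + self.p_fep_pns
        if fep_out > 1.0 + 1e-12:
            raise ValueError(
                f"FEP outgoing probabilities sum to {fep_out:.4f} > 1 "
                "(negative residual stay-probability)"
            )
        rel_out = self.p_relapse_remission + self.p_relapse_trs
        if rel_out > 1.0 + 1e-12:
            raise ValueError(
                f"RELAPSE outgoing probabilities sum to {rel_out:.4f} > 1 "
                "(negative residual stay-probability)"
            )

    @classmethod
    def from_table(cls, table) -> "TransitionParameters":
        """Build from a :class:`~eipcea.io.ParameterTable` (base-case values)."""
        return cls(
            p_fep_remission=table["p_fep_remission"],
            p_fep_trs=table["p_fep_trs"],
            p_fep_pns=table["p_fep_pns"],
            p_remission_relapse=table["p_remission_relapse"],
            p_relapse_remission=table["p_relapse_remission"],
            p_relapse_trs=table["p_relapse_trs"],
            p_relapse_inpatient=table["p_relapse_inpatient"],
            rr_remission=table["rr_remission"],
            rr_relapse=table["rr_relapse"],
            smr=table["smr"],
        )


@dataclass(frozen=True)
class StateValues:
    """Annual costs (R$) and utility weights attached to each health state."""

    annual_costs: np.ndarray  # length 6, DEATH must be 0
    utilities: np.ndarray  # length 6 in [0, 1], DEATH must be 0
    inpatient_episode_cost: float = 0.0
    eip_program_annual_cost: float = 0.0

    def __post_init__(self):
        costs = np.asarray(self.annual_costs, dtype=float)
        utils = np.asarray(self.utilities, dtype=float)
        if costs.shape != (N_STATES,) or utils.shape != (N_STATES,):
            raise ValueError(f"costs and utilities must have length {N_STATES}")
        if np.any(costs < 0):
            raise ValueError("state costs must be non-negative")
        if np.any((utils < 0) | (utils > 1)):
            raise ValueError("utilities must lie in [0, 1]")
        if costs[HealthState.DEATH] != 0 or utils[HealthState.DEATH] != 0:
            raise ValueError("DEATH must carry zero cost and zero utility")
        if self.inpatient_episode_cost < 0 or self.eip_program_annual_cost < 0:
            raise ValueError("episode and programme costs must be non-negative")
        object.__setattr__(self, "annual_costs", costs)
        object.__setattr__(self, "utilities", utils)

    @classmethod
    def from_table(cls, table) -> "StateValues":
        costs = np.zeros(N_STATES)
        utils = np.zeros(N_STATES)
        for state, key in (
            (HealthState.FEP, "fep"),
            (HealthState.REMISSION, "remission"),
            (HealthState.RELAPSE, "relapse"),
            (HealthState.TRS, "trs"),
            (HealthState.PNS, "pns"),
        ):
            costs[state] = table[f"c_{key}"]
            utils[state] = table[f"u_{key}"]
        return cls(
            annual_costs=costs,
            utilities=utils,
            inpatient_episode_cost=table["c_inpatient_episode"],
            eip_program_annual_cost=table["c_eip_program"],
        )


@dataclass(frozen=True)
class StrategySpec:
    """A treatment strategy: EIP (time-limited package) or CAPS comparator.

    ``effect_duration`` — years the risk ratios apply; ``cost_duration`` —
    years the incremental programme cost accrues; ``mortality_rr`` — optional
    scenario multiplier (< 1) on the SMR modelling a survival benefit of EIP.
    """

    name: str
    effect_duration: int = 3
    cost_duration: int = 3
    mortality_rr: float = 1.0

    def __post_init__(self):
        if self.name not in ("EIP", "CAPS"):
            raise ValueError(f"strategy name must be 'EIP' or 'CAPS', got {self.name!r}")
        if self.effect_duration < 0 or self.cost_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.mortality_rr <= 0:
            raise ValueError("mortality_rr must be positive")

    @property
    def is_eip(self) -> bool:
        return self.name == "EIP"


def _capped(p: float, cap: float, edge: str) -> float:
    cap = max(cap, 0.0)  # guard float round-off when other exits exhaust the row
    if p > cap:
        logger.warning("transition %s scaled to %.4f, capped at %.4f", edge, p, cap)
        return cap
    return p


def build_transition_matrix(
    params: TransitionParameters,
    strategy: StrategySpec,
    life_table: LifeTable,
    age: int,
    cycle_index: int,
) -> np.ndarray:
    """One-cycle 6x6 transition matrix at a given age and cycle.

    Death is applied first — ``combine_mortality(q(age), smr * mortality_rr)``
    — and the surviving mass is split by the conditional clinical
    probabilities; the residual is assigned to the stay-probability so each
    row sums to 1 exactly.  ``cycle_index`` is 0-based: the transition from
    cycle ``t`` to ``t+1`` has index ``t``, and EIP effects apply while
    ``cycle_index < effect_duration``.
    """
    q = life_table.prob(age)
    d = combine_mortality(q, params.smr * strategy.mortality_rr)

    in_effect = strategy.is_eip and cycle_index < strategy.effect_duration
    rr_rem = params.rr_remission if in_effect else 1.0
    rr_rel = params.rr_relapse if in_effect else 1.0

    fep_rem = _capped(
        params.p_fep_remission * rr_rem,
        1.0 - params.p_fep_trs - params.p_fep_pns,
        "FEP->REMISSION",
    )
    rem_rel = _capped(params.p_remission_relapse * rr_rel, 1.0, "REMISSION->RELAPSE")
    rel_rem = _capped(
        params.p_relapse_remission * rr_rem,
        1.0 - params.p_relapse_trs,
        "RELAPSE->REMISSION",
    )

    S = HealthState
    m = np.zeros((N_STATES, N_STATES))
    cond = np.zeros((N_STATES, N_STATES))
    cond[S.FEP, S.REMISSION] = fep_rem
    cond[S.FEP, S.TRS] = params.p_fep_trs
    cond[S.FEP, S.PNS] = params.p_fep_pns
    cond[S.REMISSION, S.RELAPSE] = rem_rel
    cond[S.RELAPSE, S.REMISSION] = rel_rem
    cond[S.RELAPSE, S.TRS] = params.p_relapse_trs
    # TRS and PNS are chronic: no clinical exits

    for i in range(N_STATES - 1):  # alive states
        off = (1.0 - d) * cond[i]
        m[i] = off
        m[i, S.DEATH] = d
        stay = 1.0 - d - off.sum()  # exact residual: row sums to 1
        if stay < 0.0:
            if stay < -1e-9:
                raise ValueError(
                    f"negative residual stay-probability in row {HealthState(i).name}"
                )
            stay = 0.0  # float round-off when exits exhaust the row
        m[i, i] = stay
    m[S.DEATH, S.DEATH] = 1.0
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy proportions over cycles: (horizon+1) x 6 matrix."""

    occupancy: np.ndarray
    start_age: int
    cycle_length: float = 1.0

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (cycles, {N_STATES})")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.occupancy, columns=[s.name for s in HealthState]
        )
        frame.insert(0, "cycle", np.arange(len(frame)))
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CohortResult:
    """Trace plus discounted totals and the per-cycle undiscounted accruals."""

    trace: CohortTrace
    discounted_cost: float
    discounted_qalys: float
    cycle_costs: np.ndarray  # undiscounted, index 0 unused (entry cycle)
    cycle_qalys: np.ndarray


def run_cohort(
    params: TransitionParameters,
    values: StateValues,
    strategy: StrategySpec,
    life_table: LifeTable,
    horizon: int = 10,
    discount_rate: float = 0.03,
    start_age: int = 26,
    half_cycle: bool = False,
) -> CohortResult:
    """Propagate the cohort and accrue discounted costs and QALYs.

    The cohort starts 100 % in FEP at ``start_age``; age advances one year
    per cycle.  Accrual convention: amounts for cycle ``t`` (t = 1..horizon)
    are valued from end-of-cycle occupancy and discounted by
    ``(1+r)**-t``; cycle 0 (model entry) accrues nothing.  With
    ``half_cycle=True`` the mean of start- and end-of-cycle occupancy is
    used instead (a half-cycle correction; off by default).

    Inpatient episode costs attach to the admitted fraction of new RELAPSE
    entrants each cycle; the EIP programme cost accrues on the surviving
    cohort fraction during ``cost_duration``.
    """
    if horizon < 1:
        raise ValueError(f"horizon {horizon} must be >= 1")
    if discount_rate < 0:
        raise ValueError(f"discount_rate {discount_rate} must be >= 0")
    last_age = start_age + horizon - 1
    life_table.prob(start_age)
    life_table.prob(last_age)  # raises if uncovered

    S = HealthState
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, S.FEP] = 1.0
    cycle_costs = np.zeros(horizon + 1)
    cycle_qalys = np.zeros(horizon + 1)

    for t in range(1, horizon + 1):
        m = build_transition_matrix(
            params, strategy, life_table, start_age + t - 1, t - 1
        )
        prev = occ[t - 1]
        occ[t] = prev @ m
        # new entrants into RELAPSE this cycle (excludes those already there)
        entrants = float(np.dot(np.delete(prev, S.RELAPSE), np.delete(m[:, S.RELAPSE], S.RELAPSE)))
        weight = 0.5 * (prev + occ[t]) if half_cycle else occ[t]
        qaly = float(weight @ values.utilities)
        cost = float(weight @ values.annual_costs)
        cost += entrants * params.p_relapse_inpatient * values.inpatient_episode_cost
        if strategy.is_eip and t <= strategy.cost_duration:
            alive = 1.0 - float(weight[S.DEATH])
            cost += values.eip_program_annual_cost * alive
        cycle_costs[t] = cost
        cycle_qalys[t] = qaly

    disc = (1.0 + discount_rate) ** -np.arange(horizon + 1)
    trace = CohortTrace(occupancy=occ, start_age=start_age)
    return CohortResult(
        trace=trace,
        discounted_cost=float(np.dot(cycle_costs, disc)),
        discounted_qalys=float(np.dot(cycle_qalys, disc)),
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )


def remission_at_1yr(trace: CohortTrace) -> float:
    """Proportion of the cohort in REMISSION at the end of the first cycle."""
    if trace.n_cycles < 1:
        raise ValueError("trace has no completed cycle")
    return float(trace.occupancy[1, HealthState.REMISSION])
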