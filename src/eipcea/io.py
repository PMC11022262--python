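"""Input tables, run configuration and validation.

All interchange is plain text: CSV for tables, YAML for run configuration.
Monetary values are stored in 2018 Brazilian reals (R$) at full precision;
conversion to PPP-adjusted USD happens only at report time
(:func:`eipcea.economics.convert_currency`).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterTable",
    "RunConfig",
    "ValidationError",
    "load_parameters",
    "load_life_table_csv",
    "load_trials_csv",
    "load_ipd_csv",
    "validate_config",
]


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its schema."""


#: canonical column order of the parameter table
PARAMETER_COLUMNS = ["parameter", "value", "distribution", "hyper1", "hyper2", "source"]

#: distribution families understood by the probabilistic sensitivity analysis
DISTRIBUTIONS = {"beta", "gamma", "lognormal", "fixed"}

#: every parameter the Markov engine and economics layer require
REQUIRED_PARAMETERS = [
    "p_fep_remission",
    "p_fep_trs",
    "p_fep_pns",
    "p_remission_relapse",
    "p_relapse_remission",
    "p_relapse_trs",
    "p_relapse_inpatient",
    "u_fep",
    "u_remission",
    "u_relapse",
    "u_trs",
    "u_pns",
    "c_fep",
    "c_remission",
    "c_relapse",
    "c_trs",
    "c_pns",
    "c_inpatient_episode",
    "c_eip_program",
    "smr",
    "rr_remission",
    "rr_relapse",
]


def _check_support(name: str, value: float) -> None:
    """Raise if ``value`` is outside the declared support of parameter ``name``."""
    if not np.isfinite(value):
        raise ValidationError(f"parameter {name!r}: value {value!r} is not finite")
    if name.startswith(("p_", "u_")):
        if not 0.0 <= value <= 1.0:
            raise ValidationError(
                f"parameter {name!r}: value {value} outside [0, 1]"
            )
    elif name.startswith("c_"):
        if value < 0:
            raise ValidationError(f"parameter {name!r}: cost {value} is negative")
    elif name == "smr" or name.startswith("rr_"):
        if value <= 0:
            raise ValidationError(f"parameter {name!r}: value {value} must be > 0")


class ParameterTable:
    """Model-parameter table: one row per parameter with a PSA distribution.

    Schema (CSV columns): ``parameter, value, distribution, hyper1, hyper2,
    source``.  ``value`` is the deterministic base-case point estimate;
    ``distribution``/``hyper1``/``hyper2`` parameterise the draw used in
    probabilistic sensitivity analysis:

    ``beta``       — hyper1 = a, hyper2 = b (probabilities, utilities)
    ``gamma``      — hyper1 = shape, hyper2 = scale (costs)
    ``lognormal``  — hyper1 = mean of log, hyper2 = SD of log (ratios)
    ``fixed``      — hypers ignored; the draw is the value itself
    """

    def __init__(self, frame: pd.DataFrame, *, require_complete: bool = True):
        frame = frame.copy()
        missing_cols = [c for c in PARAMETER_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValidationError(f"parameter table missing columns: {missing_cols}")
        frame = frame[PARAMETER_COLUMNS].reset_index(drop=True)
        dup = frame["parameter"][frame["parameter"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate parameter label: {dup.iloc[0]!r}")
        for _, row in frame.iterrows():
            name = str(row["parameter"])
            _check_support(name, float(row["value"]))
            dist = str(row["distribution"]).lower()
            if dist not in DISTRIBUTIONS:
                raise ValidationError(
                    f"parameter {name!r}: unknown distribution {dist!r} "
                    f"(expected one of {sorted(DISTRIBUTIONS)})"
                )
        if require_complete:
            have = set(frame["parameter"])
            missing = [p for p in REQUIRED_PARAMETERS if p not in have]
            if missing:
                raise ValidationError(
                    f"parameter table missing required parameters: {missing}"
                )
        self.frame = frame
        self._values = dict(zip(frame["parameter"], frame["value"].astype(float)))

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} not in table") from None

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, name: str) -> pd.Series:
        sel = self.frame[self.frame["parameter"] == name]
        if sel.empty:
            raise KeyError(f"parameter {name!r} not in table")
        return sel.iloc[0]

    def replace_values(self, updates: Mapping[str, float]) -> "ParameterTable":
        """Return a new table with base-case values replaced (distributions kept)."""
        frame = self.frame.copy()
        for name, value in updates.items():
            if name not in self._values:
                raise KeyError(f"parameter {name!r} not in table")
            frame.loc[frame["parameter"] == name, "value"] = float(value)
        return ParameterTable(frame)

    def as_fixed(self) -> "ParameterTable":
        """Return a copy with every distribution degenerate at the base value."""
        frame = self.frame.copy()
        frame["distribution"] = "fixed"
        return ParameterTable(frame)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw one joint parameter vector from the per-row PSA distributions.

        Draws are independent across rows.  Values are clipped into the
        open support only where the family itself can touch the boundary
        (beta draws of exactly 0/1 at extreme hypers).
        """
        out: dict[str, float] = {}
        for _, row in self.frame.iterrows():
            name = str(row["parameter"])
            dist = str(row["distribution"]).lower()
            h1, h2 = float(row["hyper1"]), float(row["hyper2"])
            if dist == "fixed":
                out[name] = float(row["value"])
            elif dist == "beta":
                out[name] = float(rng.beta(h1, h2))
            elif dist == "gamma":
                out[name] = float(rng.gamma(h1, h2))
            elif dist == "lognormal":
                out[name] = float(rng.lognormal(h1, h2))
            else:  # pragma: no cover - guarded in __init__
                raise ValidationError(f"unknown distribution {dist!r}")
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"parameter file not found: {path}")
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, columns=PARAMETER_COLUMNS)


def load_parameters(path: str | Path) -> ParameterTable:
    """Read and validate a parameter CSV; errors name the first violation."""
    return ParameterTable.from_csv(path)


# ---------------------------------------------------------------------------
# other table readers — thin pandas wrappers with schema checks
# ---------------------------------------------------------------------------

TRIALS_COLUMNS = ["trial_id", "events_t", "n_t", "events_c", "n_c"]
IPD_COLUMNS = ["subject_id", "sex", "age", "remission_12m", "relapse_12m"]


def validate_trials(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIALS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"trials table missing columns: {missing}")
    frame = frame[TRIALS_COLUMNS].reset_index(drop=True)
    for col in ("events_t", "n_t", "events_c", "n_c"):
        if (frame[col] < 0).any():
            raise ValidationError(f"trials table: negative count in column {col!r}")
    for arm in ("t", "c"):
        bad = frame[frame[f"events_{arm}"] > frame[f"n_{arm}"]]
        if len(bad):
            raise ValidationError(
                f"trial {bad['trial_id'].iloc[0]!r}: events_{arm} exceeds n_{arm}"
            )
        if (frame[f"n_{arm}"] <= 0).any():
            raise ValidationError(f"trials table: non-positive n_{arm}")
    return frame


def validate_ipd(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in IPD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"IPD table missing columns: {missing}")
    frame = frame[IPD_COLUMNS].reset_index(drop=True)
    for col in ("remission_12m", "relapse_12m"):
        if not frame[col].isin([0, 1]).all():
            raise ValidationError(f"IPD column {col!r} must be binary 0/1")
    if ((frame["age"] < 16) | (frame["age"] > 40)).any():
        raise ValidationError("IPD ages must lie in [16, 40]")
    return frame


def load_trials_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"trials file not found: {path}")
    return validate_trials(pd.read_csv(path))


def load_ipd_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"IPD file not found: {path}")
    return validate_ipd(pd.read_csv(path))


def load_life_table_csv(path: str | Path):
    """Read a life-table CSV (columns ``age, q``) into a :class:`LifeTable`."""
    from .markov import LifeTable

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"life table file not found: {path}")
    frame = pd.read_csv(path)
    for col in ("age", "q"):
        if col not in frame.columns:
            raise ValidationError(f"life table missing column {col!r}")
    return LifeTable(frame["age"].to_numpy(int), frame["q"].to_numpy(float))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with study defaults.

    Paths left as ``None`` fall back to the packaged synthetic inputs
    (generated at run time from ``seed``).  Defaults mirror the study
    conditions: 3.0 % annual discounting, 10-year horizon, model entry at
    age 26, willingness-to-pay anchored at a GDP per capita of R$ 18,254,
    5,000 PSA draws and full observational weight (alpha = 1).
    """

    parameters_csv: str | None = None
    life_table_csv: str | None = None
    trials_remission_csv: str | None = None
    trials_relapse_csv: str | None = None
    ipd_csv: str | None = None
    discount_rate: float = 0.03
    horizon: int = 10
    start_age: int = 26
    gdp_pc: float = 18_254.0
    threshold_multipliers: tuple[float, ...] = (1.0, 3.0)
    psa_draws: int = 5_000
    alpha: float = 1.0
    chains: int = 2
    iterations: int = 50_000
    burn_in: int = 5_000
    seed: int = 20_240_405
    scenarios: tuple[str, ...] = (
        "base",
        "horizon_20",
        "horizon_30",
        "lifetime_75",
        "eip_5yr",
        "mortality_effect",
    )
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("threshold_multipliers", "scenarios"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        raw = dataclasses.asdict(self)
        raw["threshold_multipliers"] = list(self.threshold_multipliers)
        raw["scenarios"] = list(self.scenarios)
        return yaml.safe_dump(raw, sort_keys=True)

    @property
    def thresholds(self) -> list[float]:
        return [m * self.gdp_pc for m in self.threshold_multipliers]

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(config: RunConfig, life_table=None) -> RunConfig:
    """Check cross-field constraints; return the config unchanged if valid.

    ``life_table`` (optional) enables the coverage check that every age the
    cohort can reach, ``start_age + horizon``, has a death probability.
    """
    if config.discount_rate < 0:
        raise ValidationError(f"discount_rate {config.discount_rate} is negative")
    if config.horizon < 1:
        raise ValidationError(f"horizon {config.horizon} must be >= 1")
    if not 0.0 <= config.alpha <= 1.0:
        raise ValidationError(f"alpha {config.alpha} outside [0, 1]")
    if config.psa_draws < 1:
        raise ValidationError(f"psa_draws {config.psa_draws} must be >= 1")
    if config.burn_in >= config.iterations:
        raise ValidationError("burn_in must be smaller than iterations")
    if any(t <= 0 for t in config.thresholds):
        raise ValidationError("willingness-to-pay thresholds must be positive")
    if life_table is not None:
        needed = config.start_age + config.horizon
        if needed > int(life_table.ages.max()):
            raise ValidationError(
                f"life table covers ages up to {int(life_table.ages.max())} "
                f"but the cohort reaches age {needed}"
            )
    return config
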