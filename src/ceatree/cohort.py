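"""Synthetic student cohorts: a microsimulation oracle for the decision tree.

Simulates individual students through the programme — supplement receipt,
vitamin D status, depression outcome — with Bernoulli draws at exactly the
branch probabilities of the cohort model, then attaches the base-case cost
and utility implied by each student's outcomes.  Cohort means therefore
converge to the tree's expected values (first-order uncertainty only;
parameter uncertainty belongs to the PSA module), which makes the
generator an independent check on the rollback arithmetic.

An adherence scenario knob scales supplement receipt in the programme arm:
1.0 reproduces the idealized decision model, while 0.785 matches the
uptake observed in the national programme.  Non-receivers behave (and are
costed) exactly like the no-intervention arm; the supplement cost is
charged only to students who actually receive it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

ARMS = ("no_intervention", "supplementation")

#: Column order of the flat per-student table (booleans encoded as 0/1).
COLUMNS = ("id", "arm", "received_supplement", "deficient", "depressed", "cost", "utility")


@dataclass(frozen=True)
class CohortParams:
    """Branch probabilities and base-case payoffs driving the simulation.

    Defaults are the cohort model's inputs: 76% deficiency without
    supplementation vs 17.2% with; depression prevalence 31.4% among the
    deficient and 16% among the sufficient; utilities 0.76 (healthy) and
    0.545 (depressed); one-year depression-management cost $335.4 and
    per-student supplement cost $0.604.
    """

    p_deficient_untreated: float = 0.76
    p_deficient_supplemented: float = 0.172
    p_depression_deficient: float = 0.314
    p_depression_sufficient: float = 0.16
    utility_healthy: float = 0.76
    utility_depressed: float = 0.545
    cost_depression: float = 335.4
    cost_supplement: float = 0.604

    def __post_init__(self) -> None:
        for name in (
            "p_deficient_untreated",
            "p_deficient_supplemented",
            "p_depression_deficient",
            "p_depression_sufficient",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} outside [0, 1]: {p}")
        for name in ("utility_healthy", "utility_depressed"):
            u = getattr(self, name)
            if not (0.0 <= u <= 1.0):
                raise ValidationError(f"{name} outside [0, 1]: {u}")
        for name in ("cost_depression", "cost_supplement"):
            c = getattr(self, name)
            if c < 0:
                raise ValidationError(f"{name} must be >= 0: {c}")

    @classmethod
    def from_model_values(cls, values: Mapping[str, float]) -> "CohortParams":
        """Build from the bundled model's parameter names."""
        return cls(
            p_deficient_untreated=values["p_deficient_untreated"],
            p_deficient_supplemented=values["p_deficient_supplemented"],
            p_depression_deficient=values["p_depression_deficient"],
            p_depression_sufficient=values["p_depression_sufficient"],
            utility_healthy=values["u_healthy"],
            utility_depressed=values["u_depressed"],
            cost_depression=values["c_depression_management"],
            cost_supplement=values["c_supplementation"],
        )


@dataclass(frozen=True)
class CohortSummary:
    """Arm-level aggregates with standard errors (sample SD / sqrt(n))."""

    arm: str
    n: int
    mean_cost: float
    mean_utility: float
    depression_rate: float
    se_cost: float
    se_utility: float
    se_depression: float
    adherence: float | None = None


def generate_cohort(
    n: int,
    params: CohortParams | None = None,
    arm: str = "no_intervention",
    adherence: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n`` students in one arm; returns a flat per-student table.

    Per student: supplement receipt ~ Bernoulli(adherence) in the
    supplementation arm (never in the comparator arm); deficiency ~
    Bernoulli(p_deficient_supplemented) if supplemented else
    Bernoulli(p_deficient_untreated); depression ~ Bernoulli of the
    status-specific prevalence; cost and utility follow deterministically.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    if arm not in ARMS:
        raise ValidationError(f"unknown arm '{arm}'; expected one of {ARMS}")
    if not (0.0 <= adherence <= 1.0):
        raise ValidationError(f"adherence outside [0, 1]: {adherence}")
    params = params or CohortParams()
    rng = np.random.default_rng(seed)

    if arm == "supplementation":
        received = rng.random(n) < adherence
    else:
        received = np.zeros(n, dtype=bool)
    p_def = np.where(
        received, params.p_deficient_supplemented, params.p_deficient_untreated
    )
    deficient = rng.random(n) < p_def
    p_dep = np.where(
        deficient, params.p_depression_deficient, params.p_depression_sufficient
    )
    depressed = rng.random(n) < p_dep

    cost = (
        depressed * params.cost_depression + received * params.cost_supplement
    ).astype(float)
    utility = np.where(
        depressed, params.utility_depressed, params.utility_healthy
    ).astype(float)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": arm,
            "received_supplement": received,
            "deficient": deficient,
            "depressed": depressed,
            "cost": cost,
            "utility": utility,
        }
    )


def summarize_cohort(
    records: pd.DataFrame, adherence: float | None = None
) -> CohortSummary:
    """Aggregate a single-arm student table into means with standard errors."""
    if len(records) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    arms = records["arm"].unique()
    if len(arms) != 1:
        raise ValidationError(
            f"summary requires a single-arm record set, got arms {sorted(arms)}"
        )
    n = len(records)

    def mean_se(x: pd.Series) -> tuple[float, float]:
        x = x.astype(float)
        sd = float(x.std(ddof=1)) if n > 1 else 0.0
        return float(x.mean()), sd / np.sqrt(n)

    mean_cost, se_cost = mean_se(records["cost"])
    mean_utility, se_utility = mean_se(records["utility"])
    dep_rate, se_dep = mean_se(records["depressed"])
    return CohortSummary(
        arm=str(arms[0]),
        n=n,
        mean_cost=mean_cost,
        mean_utility=mean_utility,
        depression_rate=dep_rate,
        se_cost=se_cost,
        se_utility=se_utility,
        se_depression=se_dep,
        adherence=adherence,
    )


def write_cohort(records: pd.DataFrame, path: str | Path) -> Path:
    """Write the student table as CSV with booleans encoded as 0/1."""
    path = Path(path)
    out = records.copy()
    for col in ("received_supplement", "deficient", "depressed"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, columns=list(COLUMNS))
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a student table written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort file missing columns {sorted(missing)}")
    for col in ("received_supplement", "deficient", "depressed"):
        df[col] = df[col].astype(bool)
    return df[list(COLUMNS)]
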