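"""Incremental cost-effectiveness analysis of two strategies.

Given the expected cost and effect of an intervention and its comparator,
this module computes the incremental cost (delta_cost), incremental effect
(delta_effect), the incremental cost-effectiveness ratio
ICER = delta_cost / delta_effect, the dominance classification, and net
monetary benefit (NMB = WTP * effect - cost) verdicts over a grid of
willingness-to-pay thresholds.

A dominant intervention (cheaper and more effective) has a negative
conventional ICER; published analyses often print the magnitude
|delta_cost| / |delta_effect| instead, so both figures are carried on the
result to keep reported tables reproducible without endorsing either sign
convention.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .tree import StrategyResult

#: |delta_effect| below this is treated as exact equivalence and the ICER
#: is left undefined rather than allowed to blow up.
EFFECT_EQUIVALENCE_TOL = 1e-12


class Dominance(str, enum.Enum):
    """Relation of the intervention to its comparator on the CE plane."""

    DOMINANT = "dominant"      # cheaper and more effective
    DOMINATED = "dominated"    # dearer and less effective
    TRADEOFF = "tradeoff"      # more effect at more cost, or the reverse
    EQUIVALENT = "equivalent"  # indistinguishable within tolerance


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison (intervention minus comparator)."""

    reference_name: str
    comparator_name: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    status: Dominance
    paper_convention_icer: float | None = None

    @property
    def cost_saving(self) -> bool:
        return self.delta_cost < 0


@dataclass(frozen=True)
class WTPVerdict:
    """Cost-effectiveness decision at one willingness-to-pay threshold."""

    wtp: float
    nmb_reference: float
    nmb_comparator: float

    @property
    def cost_effective(self) -> bool:
        return self.nmb_reference > self.nmb_comparator


def incremental_analysis(
    intervention: StrategyResult, comparator: StrategyResult
) -> IncrementalResult:
    """Delta cost/effect, ICER and dominance of intervention vs comparator."""
    dc = float(intervention.expected_cost) - float(comparator.expected_cost)
    de = float(intervention.expected_effect) - float(comparator.expected_effect)
    if not (math.isfinite(dc) and math.isfinite(de)):
        raise ValidationError("non-finite strategy results")

    effect_tie = abs(de) < EFFECT_EQUIVALENCE_TOL
    icer = None if effect_tie else dc / de

    if effect_tie and dc == 0.0:
        status = Dominance.EQUIVALENT
    elif dc < 0 and de > 0:
        status = Dominance.DOMINANT
    elif dc > 0 and de < 0:
        status = Dominance.DOMINATED
    elif effect_tie:
        # Same effect, different cost: the cheaper strategy dominates.
        status = Dominance.DOMINANT if dc < 0 else Dominance.DOMINATED
    else:
        status = Dominance.TRADEOFF

    magnitude = None
    if status is Dominance.DOMINANT and not effect_tie:
        magnitude = abs(dc) / abs(de)
    return IncrementalResult(
        reference_name=intervention.name,
        comparator_name=comparator.name,
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        status=status,
        paper_convention_icer=magnitude,
    )


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = wtp * expected_effect - expected_cost, in USD."""
    if wtp < 0:
        raise ValidationError(f"willingness to pay must be >= 0, got {wtp}")
    return wtp * float(result.expected_effect) - float(result.expected_cost)


def threshold_verdicts(
    intervention: StrategyResult,
    comparator: StrategyResult,
    wtp_grid: Sequence[float],
) -> list[WTPVerdict]:
    """One NMB-based cost-effectiveness verdict per WTP grid point."""
    if len(wtp_grid) == 0:
        raise ValidationError("wtp_grid must be non-empty")
    return [
        WTPVerdict(
            wtp=float(w),
            nmb_reference=net_monetary_benefit(intervention, w),
            nmb_comparator=net_monetary_benefit(comparator, w),
        )
        for w in wtp_grid
    ]


def results_table(
    intervention: StrategyResult,
    comparator: StrategyResult,
    inc: IncrementalResult,
) -> pd.DataFrame:
    """Base-case results as a two-row table (comparator row first)."""
    rows = [
        {
            "strategy": comparator.name,
            "cost": float(comparator.expected_cost),
            "incr_cost": inc.delta_cost,
            "effect": float(comparator.expected_effect),
            "incr_effect": inc.delta_effect,
            "icer": inc.icer,
            "icer_magnitude": inc.paper_convention_icer,
            "status": "",
        },
        {
            "strategy": intervention.name,
            "cost": float(intervention.expected_cost),
            "incr_cost": 0.0,
            "effect": float(intervention.expected_effect),
            "incr_effect": 0.0,
            "icer": None,
            "icer_magnitude": None,
            "status": inc.status.value,
        },
    ]
    return pd.DataFrame(rows)


def write_results(
    table: pd.DataFrame,
    inc: IncrementalResult,
    verdicts: Sequence[WTPVerdict],
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the base-case table as CSV and JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "basecase.csv"
    json_path = out_dir / "basecase.json"
    table.to_csv(csv_path, index=False)
    payload = {
        "metadata": metadata or {},
        "strategies": table.where(table.notna(), None).to_dict(orient="records"),
        "incremental": {
            **{k: v for k, v in asdict(inc).items() if k != "status"},
            "status": inc.status.value,
        },
        "wtp_verdicts": [
            {
                "wtp": v.wtp,
                "nmb_reference": v.nmb_reference,
                "nmb_comparator": v.nmb_comparator,
                "cost_effective": v.cost_effective,
            }
            for v in verdicts
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return {"csv": csv_path, "json": json_path}
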