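"""Probabilistic sensitivity analysis by Monte Carlo simulation.

Each iteration draws one value of every uncertain parameter (utilities and
costs; branch probabilities carry no uncertainty and stay at their base
values), evaluates both strategies with that common parameter set, and
records the incremental cost and effect of the intervention.  The draws
feed the cost-effectiveness plane, the cost-effectiveness acceptability
curve (CEAC) and strategy-selection frequencies.

Sampling one draw per parameter shared across arms (common random
parameters) reflects that the utilities and the depression cost are the
same quantities in both strategies; sampling them independently per arm
would overstate the variance of the increments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Model
from .errors import ValidationError
from .tree import rollback

#: Default CEAC grid: $0 to $5000 per QALY in $50 steps, always including
#: the decision thresholds 1032 and 2666 USD/QALY.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(
    sorted(set(np.arange(0.0, 5001.0, 50.0)) | {1032.0, 2666.0})
)

QUADRANTS = ("NE", "NW", "SE", "SW")


@dataclass(frozen=True)
class PSADraws:
    """Per-iteration sampled parameters and incremental (cost, effect) pairs."""

    n_iter: int
    seed: int
    intervention_name: str
    comparator_name: str
    delta_costs: np.ndarray
    delta_effects: np.ndarray
    samples: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in (
            ("delta_costs", self.delta_costs),
            ("delta_effects", self.delta_effects),
            *self.samples.items(),
        ):
            if len(arr) != self.n_iter:
                raise ValidationError(
                    f"'{name}' has length {len(arr)}, expected n_iter={self.n_iter}"
                )

    def incremental_nmb(self, wtp: float) -> np.ndarray:
        """Per-draw incremental net monetary benefit at one WTP."""
        if wtp < 0:
            raise ValidationError(f"willingness to pay must be >= 0, got {wtp}")
        return wtp * self.delta_effects - self.delta_costs


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP."""

    wtp: float
    acceptability: float


def run_psa(model: Model, n_iter: int = 10_000, seed: int = 0) -> PSADraws:
    """Monte Carlo PSA of ``model.intervention`` vs ``model.comparator``.

    Reproducible for a given seed: parameters are sampled in sorted name
    order from one generator, then both strategies are rolled back with
    the sampled values (vectorized over all iterations at once).
    """
    if n_iter < 1:
        raise ValidationError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    params: dict[str, float | np.ndarray] = dict(model.base_values())
    samples: dict[str, np.ndarray] = {}
    for name in sorted(model.uncertain_parameters):
        draws = model.parameters[name].spec.sample(rng, n_iter)
        samples[name] = draws
        params[name] = draws
    res_int = rollback(model.strategy(model.intervention), params)
    res_comp = rollback(model.strategy(model.comparator), params)
    dc = np.broadcast_to(
        np.asarray(res_int.expected_cost - res_comp.expected_cost, dtype=float),
        (n_iter,),
    ).copy()
    de = np.broadcast_to(
        np.asarray(res_int.expected_effect - res_comp.expected_effect, dtype=float),
        (n_iter,),
    ).copy()
    return PSADraws(
        n_iter=n_iter,
        seed=seed,
        intervention_name=model.intervention,
        comparator_name=model.comparator,
        delta_costs=dc,
        delta_effects=de,
        samples=samples,
    )


def classify_quadrants(draws: PSADraws) -> dict[str, int]:
    """Count draws per cost-effectiveness-plane quadrant.

    East/west by the sign of delta_effect, north/south by the sign of
    delta_cost; a draw exactly on an axis (zero) is assigned to the
    positive side (east resp. north).  SE — more effect at lower cost — is
    the dominance quadrant.
    """
    if draws.n_iter == 0:
        raise ValidationError("no draws to classify")
    east = draws.delta_effects >= 0
    north = draws.delta_costs >= 0
    return {
        "NE": int(np.sum(east & north)),
        "NW": int(np.sum(~east & north)),
        "SE": int(np.sum(east & ~north)),
        "SW": int(np.sum(~east & ~north)),
    }


def quadrant_labels(draws: PSADraws) -> np.ndarray:
    """Per-draw quadrant label, same tie convention as classify_quadrants."""
    east = draws.delta_effects >= 0
    north = draws.delta_costs >= 0
    labels = np.where(
        east, np.where(north, "NE", "SE"), np.where(north, "NW", "SW")
    )
    return labels


def ceac(draws: PSADraws, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each threshold, the acceptability is the fraction of draws with
    strictly positive incremental net monetary benefit.
    """
    if len(wtp_grid) == 0:
        raise ValidationError("wtp_grid must be non-empty")
    grid = np.asarray(wtp_grid, dtype=float)
    if np.any(grid < 0):
        raise ValidationError("wtp_grid entries must be >= 0")
    # (n_wtp, n_iter) NMB matrix; strict inequality counts as acceptable.
    nmb = grid[:, None] * draws.delta_effects[None, :] - draws.delta_costs[None, :]
    acc = (nmb > 0).mean(axis=1)
    return [CEACPoint(float(w), float(a)) for w, a in zip(grid, acc)]


def strategy_selection(draws: PSADraws, wtp: float) -> dict[str, float]:
    """Fraction of draws in which each strategy is the cost-effective choice."""
    acc = float(np.mean(draws.incremental_nmb(wtp) > 0))
    return {
        draws.intervention_name: acc,
        draws.comparator_name: 1.0 - acc,
    }


def ce_plane_frame(draws: PSADraws) -> pd.DataFrame:
    """CE-plane scatter data: one row per draw with its quadrant label."""
    return pd.DataFrame(
        {
            "delta_effect": draws.delta_effects,
            "delta_cost": draws.delta_costs,
            "quadrant": quadrant_labels(draws),
        }
    )


def write_psa_outputs(
    draws: PSADraws,
    out_dir: str | Path,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    selection_wtp: float = 2666.0,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write CE-plane CSV, CEAC CSV and selection-frequency JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": draws.seed, "n_iter": draws.n_iter, **(metadata or {})}
    header = "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))

    plane_path = out_dir / "ce_plane.csv"
    with open(plane_path, "w") as fh:
        fh.write(header)
        ce_plane_frame(draws).to_csv(fh, index=False)

    ceac_path = out_dir / "ceac.csv"
    curve = ceac(draws, wtp_grid)
    with open(ceac_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(
            {"wtp": [p.wtp for p in curve], "acceptability": [p.acceptability for p in curve]}
        ).to_csv(fh, index=False)

    sel_path = out_dir / "selection.json"
    sel_path.write_text(
        json.dumps(
            {
                "metadata": meta,
                "wtp": selection_wtp,
                "frequencies": strategy_selection(draws, selection_wtp),
            },
            indent=2,
        )
        + "\n"
    )
    return {"ce_plane": plane_path, "ceac": ceac_path, "selection": sel_path}
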