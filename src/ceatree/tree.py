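"""Decision-tree structure and expected-value rollback.

A strategy is a (possibly nested) tree of chance nodes whose leaves carry a
one-period cost and a utility.  Rolling the tree back computes the
probability-weighted expectation of both payoffs over all root-to-leaf
paths; an optional strategy-level upfront cost (e.g. a per-person programme
cost incurred regardless of outcome) is added outside the chance tree.

Payoffs and branch probabilities may be numeric literals or references (by
name) to model parameters; rollback resolves references against a mapping
of parameter values.  Because rollback is a weighted sum, parameter values
may be NumPy arrays, in which case the result is the vectorized rollback
over all draws at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import numpy as np

from .errors import EvaluationError

#: Absolute tolerance for branch probabilities summing to one.  Model
#: inputs are exact decimals, so only accumulated float error is allowed.
PROB_SUM_TOL = 1e-9

ParamValue = Union[float, np.ndarray]
Ref = Union[float, int, str]


def resolve(x: Ref, params: Mapping[str, ParamValue]) -> ParamValue:
    """Resolve a literal or named parameter reference to its value."""
    if isinstance(x, str):
        try:
            return params[x]
        except KeyError:
            raise EvaluationError(f"unresolved parameter reference '{x}'") from None
    return float(x)


@dataclass(frozen=True)
class TerminalNode:
    """Leaf payoffs: one-period cost (USD) and utility (QALY weight)."""

    cost: Ref
    utility: Ref
    tags: frozenset = frozenset()
    label: str = ""


@dataclass(frozen=True)
class Branch:
    probability: Ref
    child: "Node"
    label: str = ""


@dataclass(frozen=True)
class ChanceNode:
    """A probabilistic branching; branch probabilities must sum to one."""

    branches: tuple[Branch, ...]
    label: str = ""


Node = Union[ChanceNode, TerminalNode]


@dataclass(frozen=True)
class Strategy:
    """A named decision alternative: upfront cost plus a chance tree."""

    name: str
    root: Node
    upfront_cost: Ref = 0.0


@dataclass(frozen=True)
class StrategyResult:
    """Expected cost (USD) and expected effect (QALY) of one strategy."""

    name: str
    expected_cost: ParamValue
    expected_effect: ParamValue


def iter_paths(
    node: Node, params: Mapping[str, ParamValue]
) -> Iterator[tuple[ParamValue, TerminalNode]]:
    """Yield (path probability, leaf) over every root-to-leaf path."""
    if isinstance(node, TerminalNode):
        yield 1.0, node
        return
    for branch in node.branches:
        p = resolve(branch.probability, params)
        for sub_p, leaf in iter_paths(branch.child, params):
            yield p * sub_p, leaf


def validate_tree(
    strategy: Strategy, params: Mapping[str, ParamValue] | None = None
) -> list[str]:
    """Structural and probabilistic checks; returns human-readable violations.

    An empty list means every chance node's branch probabilities sum to one
    within :data:`PROB_SUM_TOL`, every node has at least two branches, and
    every leaf payoff satisfies its type invariants (cost >= 0, utility in
    [0, 1]).  Loaders raise on a non-empty result; callers exploring a
    model in memory get the full list instead of the first failure.
    """
    params = params or {}
    violations: list[str] = []

    def resolve_or_report(x: Ref, where: str) -> float | None:
        try:
            v = resolve(x, params)
        except EvaluationError as exc:
            violations.append(f"{where}: {exc}")
            return None
        return float(v)

    def walk(node: Node, path: str) -> None:
        if isinstance(node, TerminalNode):
            cost = resolve_or_report(node.cost, f"{path}/cost")
            util = resolve_or_report(node.utility, f"{path}/utility")
            if cost is not None and not (cost >= 0 and np.isfinite(cost)):
                violations.append(f"{path}: terminal cost must be finite and >= 0, got {cost}")
            if util is not None and not (0.0 <= util <= 1.0):
                violations.append(f"{path}: terminal utility outside [0, 1]: {util}")
            return
        if len(node.branches) < 2:
            violations.append(
                f"{path}: chance node needs >= 2 branches, has {len(node.branches)}"
            )
        total = 0.0
        ok = True
        for i, branch in enumerate(node.branches):
            where = f"{path}/{branch.label or i}"
            p = resolve_or_report(branch.probability, f"{where}@p")
            if p is None:
                ok = False
            else:
                if not (0.0 <= p <= 1.0):
                    violations.append(f"{where}: probability outside [0, 1]: {p}")
                    ok = False
                total += p
            walk(branch.child, where)
        if ok and abs(total - 1.0) > PROB_SUM_TOL:
            violations.append(
                f"{path}: branch probabilities sum to {total:.12g}, expected 1"
            )

    walk(strategy.root, strategy.name)
    up = resolve_or_report(strategy.upfront_cost, f"{strategy.name}@upfront_cost")
    if up is not None and up < 0:
        violations.append(f"{strategy.name}: upfront cost must be >= 0, got {up}")
    return violations


def rollback(strategy: Strategy, params: Mapping[str, ParamValue]) -> StrategyResult:
    """Expected cost and effect by probability-weighted rollback.

    expected_cost = upfront + sum over leaves of P(path) * leaf cost;
    expected_effect = sum of P(path) * leaf utility.  Linear in every
    payoff, so array-valued parameters vectorize draw-wise.
    """
    cost = resolve(strategy.upfront_cost, params) + 0.0
    effect = 0.0
    for p, leaf in iter_paths(strategy.root, params):
        cost = cost + p * resolve(leaf.cost, params)
        effect = effect + p * resolve(leaf.utility, params)
    return StrategyResult(strategy.name, cost, effect)


def outcome_probability(
    strategy: Strategy, params: Mapping[str, ParamValue], tag: str = "depressed"
) -> ParamValue:
    """Total path probability into leaves carrying ``tag``.

    With the default tag this is the strategy's depression prevalence.
    Raises :class:`EvaluationError` if no leaf in the tree carries the tag.
    """
    leaves = list(iter_paths(strategy.root, params))
    if not any(tag in leaf.tags for _, leaf in leaves):
        raise EvaluationError(
            f"strategy '{strategy.name}' has no leaf tagged '{tag}'"
        )
    total: ParamValue = 0.0
    for p, leaf in leaves:
        if tag in leaf.tags:
            total = total + p
    return total
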