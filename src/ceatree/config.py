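"""Declarative model files: schema, loading and validation.

A model file is YAML with three top-level blocks::

    name: <model id>
    intervention: <strategy name>      # the strategy under evaluation
    comparator: <strategy name>        # the do-nothing / status-quo arm
    wtp_thresholds: [<USD/QALY>, ...]  # optional decision thresholds

    parameters:
      <name>:
        role: probability | utility | cost
        # fixed parameters:      value: <number>
        # uncertain parameters:  family: gamma|beta, mean: <m>, sd: <s>
        units: <free text, optional>

    strategies:
      - name: <unique name>
        upfront_cost: <number or parameter name>   # optional, default 0
        root: <node>

    # a chance node:
    #   label: <text>
    #   branches:
    #     - {label: <text>, p: <number | parameter name | complement>, node: <node>}
    # a terminal node:
    #   {cost: <number | parameter name>, utility: <number | parameter name>,
    #    tags: [<outcome labels>]}

``p: complement`` (allowed on at most one branch per node) assigns the
probability mass left over by the sibling branches; it exists because
published inputs sometimes state complementary percentages that do not sum
exactly to one, and the complement form makes the normalization choice
explicit in the model file.

Every parameter reference must resolve and every chance node's
probabilities must sum to one; violations raise :class:`ConfigError`
naming the offending node path.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError, ValidationError
from .parameters import DistributionSpec, Family, Parameter, Role
from .tree import (
    Branch,
    ChanceNode,
    Strategy,
    TerminalNode,
    resolve,
    validate_tree,
)

_COMPLEMENT = "complement"


@dataclass(frozen=True)
class Model:
    """A validated two-strategy decision model plus its parameter set."""

    name: str
    strategies: tuple[Strategy, ...]
    parameters: dict[str, Parameter]
    intervention: str
    comparator: str
    wtp_thresholds: tuple[float, ...] = ()
    checksum: str = ""

    def base_values(self) -> dict[str, float]:
        """Point-estimate value of every parameter (distribution means)."""
        return {name: p.value for name, p in self.parameters.items()}

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def uncertain_parameters(self) -> dict[str, Parameter]:
        """Parameters that are sampled in probabilistic sensitivity analysis."""
        return {n: p for n, p in self.parameters.items() if not p.spec.is_fixed}


def _parse_parameter(name: str, raw: Mapping[str, Any]) -> Parameter:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"parameter '{name}': expected a mapping, got {raw!r}")
    try:
        role = Role(raw["role"])
    except KeyError:
        raise ConfigError(f"parameter '{name}': missing 'role'") from None
    except ValueError:
        raise ConfigError(
            f"parameter '{name}': unknown role '{raw['role']}'"
        ) from None
    try:
        if "value" in raw:
            spec = DistributionSpec(Family.FIXED, float(raw["value"]), 0.0, name)
        else:
            family = Family(raw["family"])
            spec = DistributionSpec(
                family, float(raw["mean"]), float(raw["sd"]), name
            )
    except KeyError as exc:
        raise ConfigError(f"parameter '{name}': missing {exc}") from None
    except ValueError as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ConfigError(
            f"parameter '{name}': unknown distribution family '{raw.get('family')}'"
        ) from None
    return Parameter(name, role, spec, str(raw.get("units", "")))


def _parse_node(raw: Any, path: str, base: Mapping[str, float]):
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a node mapping, got {raw!r}")
    if "branches" in raw:
        branches = raw["branches"]
        if not isinstance(branches, list) or not branches:
            raise ConfigError(f"{path}: 'branches' must be a non-empty list")
        parsed: list[Branch] = []
        complement_at: int | None = None
        mass = 0.0
        for i, braw in enumerate(branches):
            label = str(braw.get("label", i))
            where = f"{path}/{label}"
            if "p" not in braw:
                raise ConfigError(f"{where}: branch missing probability 'p'")
            p = braw["p"]
            child = _parse_node(braw.get("node"), where, base)
            if isinstance(p, str) and p == _COMPLEMENT:
                if complement_at is not None:
                    raise ConfigError(
                        f"{path}: more than one 'complement' branch"
                    )
                complement_at = i
                parsed.append(Branch(0.0, child, label))
                continue
            if isinstance(p, str) and p not in base:
                raise ConfigError(f"{where}: unknown parameter reference '{p}'")
            parsed.append(Branch(p, child, label))
            mass += float(resolve(p, base))
        if complement_at is not None:
            rest = 1.0 - mass
            if rest < -1e-12:
                raise ConfigError(
                    f"{path}: sibling probabilities exceed 1 ({mass:.12g}), "
                    "no mass left for the complement branch"
                )
            old = parsed[complement_at]
            parsed[complement_at] = Branch(max(rest, 0.0), old.child, old.label)
        return ChanceNode(tuple(parsed), str(raw.get("label", "")))
    if "cost" in raw and "utility" in raw:
        for key in ("cost", "utility"):
            v = raw[key]
            if isinstance(v, str) and v not in base:
                raise ConfigError(
                    f"{path}: unknown parameter reference '{v}' in '{key}'"
                )
        tags = frozenset(str(t) for t in raw.get("tags", ()))
        return TerminalNode(raw["cost"], raw["utility"], tags, str(raw.get("label", "")))
    raise ConfigError(
        f"{path}: a node needs either 'branches' or both 'cost' and 'utility'"
    )


def _parse_strategy(raw: Mapping[str, Any], base: Mapping[str, float]) -> Strategy:
    if "name" not in raw:
        raise ConfigError("strategy missing 'name'")
    name = str(raw["name"])
    upfront = raw.get("upfront_cost", 0.0)
    if isinstance(upfront, str) and upfront not in base:
        raise ConfigError(
            f"strategy '{name}': unknown parameter reference '{upfront}' "
            "in 'upfront_cost'"
        )
    root = _parse_node(raw.get("root"), name, base)
    return Strategy(name, root, upfront)


def load_model_config(path: str | Path) -> Model:
    """Load, parse and fully validate a model file.

    Returns a :class:`Model` whose trees have already passed
    :func:`ceatree.tree.validate_tree` against the base-case parameter
    values; any violation raises :class:`ConfigError` with the path to the
    offending node.
    """
    path = Path(path)
    data = path.read_bytes()
    checksum = hashlib.sha256(data).hexdigest()
    try:
        raw = yaml.safe_load(data)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from None
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in ("name", "parameters", "strategies"):
        if key not in raw:
            raise ConfigError(f"{path}: missing top-level '{key}'")

    parameters = {
        name: _parse_parameter(name, spec)
        for name, spec in raw["parameters"].items()
    }
    base = {name: p.value for name, p in parameters.items()}

    strategies = tuple(_parse_strategy(s, base) for s in raw["strategies"])
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ConfigError(f"{path}: duplicate strategy names {names}")

    intervention = str(raw.get("intervention", names[-1]))
    comparator = str(raw.get("comparator", names[0]))
    for role, sname in (("intervention", intervention), ("comparator", comparator)):
        if sname not in names:
            raise ConfigError(f"{path}: {role} '{sname}' is not a strategy")

    for s in strategies:
        violations = validate_tree(s, base)
        if violations:
            raise ConfigError(
                f"{path}: invalid tree:\n  " + "\n  ".join(violations)
            )

    wtp = tuple(float(w) for w in raw.get("wtp_thresholds", ()))
    return Model(
        name=str(raw["name"]),
        strategies=strategies,
        parameters=parameters,
        intervention=intervention,
        comparator=comparator,
        wtp_thresholds=wtp,
        checksum=checksum,
    )


def bundled_model_path(name: str = "vitd_iran_2018") -> Path:
    """Filesystem path of a model file shipped with the package."""
    ref = resources.files("ceatree") / "models" / f"{name}.yaml"
    return Path(str(ref))


def load_bundled_model(name: str = "vitd_iran_2018") -> Model:
    """Load a model shipped with the package by short name."""
    return load_model_config(bundled_model_path(name))
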