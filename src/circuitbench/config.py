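"""Hierarchical parameter trees: the declarative configuration front-end.

Model, sheet and connector blocks are configured through nested parameter
trees written in a restricted Python-literal dialect: dictionaries, numeric /
string / boolean / tuple scalars, ``url("relative/path")`` file inclusion,
``ref('dotted.path')`` references into the tree, ``UniformDist(min=, max=)``
(or the equivalent ``PyNNDistribution(name='uniform', params=(a, b))``)
distribution literals, and arithmetic expressions (``+ - * /``, parentheses)
over references and numeric literals.

Loading inlines every include (paths resolve relative to the including
file); :func:`resolve_references` then replaces references by the referenced
values with fixed-point iteration, so that forward references and chains of
references work, and evaluates arithmetic.  Validation checks a resolved
tree against a :class:`ParamSpec` of required names and type tags.
"""

from __future__ import annotations

import ast
import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "Reference",
    "Expression",
    "ParamTree",
    "ParamSpec",
    "load_param_tree",
    "parse_param_text",
    "resolve_references",
    "validate",
    "override",
    "sample_distribution",
    "serialize_param_tree",
]


class ConfigError(ValueError):
    """Raised for parse errors, dangling references, include cycles, etc."""


@dataclass(frozen=True)
class DistributionSpec:
    """A random-distribution literal (currently the uniform family only)."""

    family: str
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.family != "uniform":
            raise ConfigError(f"unsupported distribution family {self.family!r}")
        if self.min > self.max:
            raise ConfigError(f"distribution min {self.min} > max {self.max}")


@dataclass(frozen=True)
class Reference:
    """An unresolved ``ref('dotted.path')`` node."""

    path: str


@dataclass(frozen=True)
class Expression:
    """An unresolved arithmetic expression over references and numbers.

    ``op`` is one of ``+ - * / neg``; ``args`` holds one or two operands,
    each a number, :class:`Reference` or nested :class:`Expression`.
    """

    op: str
    args: tuple


class ParamTree:
    """A nested mapping of configuration keys to values.

    Thin ordered-dict wrapper with dotted-path access.  Values are scalars,
    tuples, :class:`DistributionSpec`, nested :class:`ParamTree`, or (before
    resolution) :class:`Reference` / :class:`Expression` nodes.
    """

    def __init__(self, items: Mapping[str, Any] | None = None):
        self._items: dict[str, Any] = {}
        if items:
            for k, v in items.items():
                self[k] = v

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> Any:
        return self._items[key]

    def __setitem__(self, key: str, value: Any) -> None:
        if isinstance(value, dict):
            value = ParamTree(value)
        self._items[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self._items

    def __iter__(self) -> Iterator[str]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def keys(self):
        return self._items.keys()

    def items(self):
        return self._items.items()

    def values(self):
        return self._items.values()

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ParamTree):
            return self._items == other._items
        return NotImplemented

    def __repr__(self) -> str:
        return f"ParamTree({self._items!r})"

    # -- dotted-path access -----------------------------------------------
    def get_path(self, path: str) -> Any:
        node: Any = self
        for part in path.split("."):
            if not isinstance(node, ParamTree) or part not in node:
                raise KeyError(path)
            node = node[part]
        return node

    def has_path(self, path: str) -> bool:
        try:
            self.get_path(path)
            return True
        except KeyError:
            return False

    def set_path(self, path: str, value: Any) -> None:
        parts = path.split(".")
        node = self
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], ParamTree):
                raise KeyError(path)
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(path)
        node[parts[-1]] = value

    def copy(self) -> "ParamTree":
        out = ParamTree()
        for k, v in self._items.items():
            out._items[k] = v.copy() if isinstance(v, ParamTree) else copy.deepcopy(v)
        return out

    def to_dict(self) -> dict:
        """Plain-dict view (nested ParamTrees become dicts)."""
        return {
            k: (v.to_dict() if isinstance(v, ParamTree) else v)
            for k, v in self._items.items()
        }

    def leaf_paths(self) -> list[str]:
        out = []
        for k, v in self._items.items():
            if isinstance(v, ParamTree):
                out.extend(f"{k}.{p}" for p in v.leaf_paths())
            else:
                out.append(k)
        return out


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_BINOPS = {ast.Add: "+", ast.Sub: "-", ast.Mult: "*", ast.Div: "/"}


class _Parser:
    def __init__(self, base_dir: Path | None, include_stack: tuple[Path, ...]):
        self.base_dir = base_dir
        self.include_stack = include_stack

    def convert(self, node: ast.expr) -> Any:
        if isinstance(node, ast.Dict):
            tree = ParamTree()
            for knode, vnode in zip(node.keys, node.values):
                if not (isinstance(knode, ast.Constant) and isinstance(knode.value, str)):
                    raise ConfigError(
                        f"line {knode.lineno if knode else '?'}: keys must be strings"
                    )
                key = knode.value
                if key in tree:
                    raise ConfigError(f"line {knode.lineno}: duplicate key {key!r}")
                tree[key] = self.convert(vnode)
            return tree
        if isinstance(node, ast.Constant):
            if isinstance(node.value, (int, float, str, bool)) or node.value is None:
                return node.value
            raise ConfigError(f"line {node.lineno}: unsupported literal {node.value!r}")
        if isinstance(node, ast.Tuple):
            return tuple(self.convert(e) for e in node.elts)
        if isinstance(node, ast.List):
            return [self.convert(e) for e in node.elts]
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            operand = self.convert(node.operand)
            if isinstance(operand, (int, float)):
                return -operand
            return Expression("neg", (operand,))
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            left, right = self.convert(node.left), self.convert(node.right)
            if isinstance(left, (int, float)) and isinstance(right, (int, float)):
                return _apply_op(_BINOPS[type(node.op)], left, right)
            return Expression(_BINOPS[type(node.op)], (left, right))
        if isinstance(node, ast.Call):
            return self._convert_call(node)
        raise ConfigError(
            f"line {getattr(node, 'lineno', '?')}: unsupported syntax "
            f"{ast.dump(node, include_attributes=False)[:60]}"
        )

    def _convert_call(self, node: ast.Call) -> Any:
        if not isinstance(node.func, ast.Name):
            raise ConfigError(f"line {node.lineno}: unsupported call")
        name = node.func.id
        args = [self.convert(a) for a in node.args]
        kwargs = {kw.arg: self.convert(kw.value) for kw in node.keywords}
        if name == "ref":
            if len(args) != 1 or kwargs or not isinstance(args[0], str):
                raise ConfigError(f"line {node.lineno}: ref() takes one string")
            return Reference(args[0])
        if name == "url":
            if len(args) != 1 or kwargs or not isinstance(args[0], str):
                raise ConfigError(f"line {node.lineno}: url() takes one string")
            return self._load_include(args[0], node.lineno)
        if name == "UniformDist":
            try:
                return DistributionSpec("uniform", float(kwargs["min"]), float(kwargs["max"]))
            except KeyError as exc:
                raise ConfigError(f"line {node.lineno}: UniformDist needs min=, max=") from exc
        if name == "PyNNDistribution":
            if kwargs.get("name") != "uniform":
                raise ConfigError(f"line {node.lineno}: only uniform PyNNDistribution supported")
            lo, hi = kwargs["params"]
            return DistributionSpec("uniform", float(lo), float(hi))
        raise ConfigError(f"line {node.lineno}: unknown constructor {name!r}")

    def _load_include(self, relpath: str, lineno: int) -> Any:
        if self.base_dir is None:
            raise ConfigError(f"line {lineno}: url() not allowed without a file context")
        if Path(relpath).is_absolute():
            raise ConfigError(f"line {lineno}: url() paths must be relative, got {relpath!r}")
        path = (self.base_dir / relpath).resolve()
        if not path.exists() and path.with_suffix(".param").exists():
            path = path.with_suffix(".param")
        if path in self.include_stack:
            cycle = " -> ".join(str(p) for p in (*self.include_stack, path))
            raise ConfigError(f"include cycle: {cycle}")
        return _load(path, self.include_stack)


def _apply_op(op: str, left: float, right: float) -> float:
    if op == "+":
        return left + right
    if op == "-":
        return left - right
    if op == "*":
        return left * right
    if right == 0:
        raise ConfigError("division by zero in parameter expression")
    return left / right


def parse_param_text(text: str, base_dir: str | Path | None = None) -> ParamTree:
    """Parse one configuration document from ``text``.

    ``base_dir`` anchors relative ``url()`` includes; without it, includes
    are rejected.
    """
    try:
        expr = ast.parse(text.strip() or "{}", mode="eval").body
    except SyntaxError as exc:
        raise ConfigError(f"parse error at line {exc.lineno}: {exc.msg}") from exc
    result = _Parser(Path(base_dir) if base_dir else None, ()).convert(expr)
    if not isinstance(result, ParamTree):
        raise ConfigError("a configuration document must be a mapping at top level")
    return result


def _load(path: Path, include_stack: tuple[Path, ...]) -> ParamTree:
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        expr = ast.parse(text.strip() or "{}", mode="eval").body
    except SyntaxError as exc:
        raise ConfigError(f"{path}: parse error at line {exc.lineno}: {exc.msg}") from exc
    result = _Parser(path.parent, (*include_stack, path)).convert(expr)
    if not isinstance(result, ParamTree):
        raise ConfigError(f"{path}: document must be a mapping at top level")
    return result


def load_param_tree(path: str | Path) -> ParamTree:
    """Load a configuration file, inlining ``url()`` includes.

    References and arithmetic expressions are preserved unresolved; follow
    with :func:`resolve_references`.
    """
    return _load(Path(path).resolve(), ())


# ---------------------------------------------------------------------------
# Reference resolution
# ---------------------------------------------------------------------------

def _is_unresolved(value: Any) -> bool:
    if isinstance(value, (Reference, Expression)):
        return True
    if isinstance(value, ParamTree):
        return any(_is_unresolved(v) for v in value.values())
    return False


def _try_resolve(value: Any, root: ParamTree) -> tuple[Any, bool]:
    """Return (new value, fully_resolved)."""
    if isinstance(value, Reference):
        try:
            target = root.get_path(value.path)
        except KeyError:
            return value, False
        if _is_unresolved(target):
            return value, False
        return (target.copy() if isinstance(target, ParamTree) else copy.deepcopy(target)), True
    if isinstance(value, Expression):
        resolved_args = []
        for arg in value.args:
            new, ok = _try_resolve(arg, root)
            if not ok:
                return value, False
            resolved_args.append(new)
        for arg in resolved_args:
            if not isinstance(arg, (int, float)) or isinstance(arg, bool):
                raise ConfigError(
                    f"arithmetic on non-numeric value {arg!r} in parameter expression"
                )
        if value.op == "neg":
            return -resolved_args[0], True
        return _apply_op(value.op, *resolved_args), True
    if isinstance(value, ParamTree):
        all_ok = True
        for k in list(value.keys()):
            new, ok = _try_resolve(value[k], root)
            value[k] = new
            all_ok = all_ok and ok
        return value, all_ok
    return value, True


def _collect_dangling(value: Any, root: ParamTree, out: list[str]) -> None:
    if isinstance(value, Reference):
        out.append(value.path)
    elif isinstance(value, Expression):
        for a in value.args:
            _collect_dangling(a, root, out)
    elif isinstance(value, ParamTree):
        for v in value.values():
            _collect_dangling(v, root, out)


def resolve_references(tree: ParamTree) -> ParamTree:
    """Replace references and evaluate arithmetic; returns a new tree.

    Resolution iterates to a fixed point (bounded by node count) so chains
    and forward references work; an unresolvable residue means a dangling
    path or a cycle.
    """
    out = tree.copy()
    # +2 iterations headroom: each pass resolves at least one node or stalls
    max_rounds = _count_nodes(out) + 2
    for _ in range(max_rounds):
        before = _count_unresolved(out)
        if before == 0:
            return out
        _try_resolve(out, out)
        after = _count_unresolved(out)
        if after == before:
            dangling: list[str] = []
            _collect_dangling(out, out, dangling)
            missing = [p for p in dangling if not tree.has_path(p)]
            if missing:
                raise ConfigError(f"dangling reference path(s): {sorted(set(missing))}")
            raise ConfigError(f"reference cycle involving path(s): {sorted(set(dangling))}")
        if after == 0:
            return out
    raise ConfigError("reference resolution did not converge")  # pragma: no cover


def _count_nodes(value: Any) -> int:
    if isinstance(value, ParamTree):
        return 1 + sum(_count_nodes(v) for v in value.values())
    return 1


def _count_unresolved(value: Any) -> int:
    if isinstance(value, (Reference, Expression)):
        return 1
    if isinstance(value, ParamTree):
        return sum(_count_unresolved(v) for v in value.values())
    return 0


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ParamSpec:
    """Required-parameter specification: name -> type tag.

    Type tags: ``"number"``, ``"string"``, ``"boolean"``, ``"tuple"``,
    ``"distribution"``, a nested :class:`ParamSpec`, or ``"any"``.
    """

    entries: dict[str, Any] = field(default_factory=dict)


@dataclass
class ValidationReport:
    missing: list[str] = field(default_factory=list)
    type_mismatches: list[str] = field(default_factory=list)
    unknown: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.type_mismatches or self.unknown)

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "valid"
        lines = []
        for p in self.missing:
            lines.append(f"missing: {p}")
        for p in self.type_mismatches:
            lines.append(f"type mismatch: {p}")
        for p in self.unknown:
            lines.append(f"unknown key: {p}")
        return "\n".join(lines)


def _type_ok(value: Any, tag: Any) -> bool:
    if tag == "any":
        return True
    if tag == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool) or isinstance(
            value, DistributionSpec
        )
    if tag == "string":
        return isinstance(value, str)
    if tag == "boolean":
        return isinstance(value, bool)
    if tag == "tuple":
        return isinstance(value, (tuple, list))
    if tag == "distribution":
        return isinstance(value, DistributionSpec)
    raise ConfigError(f"unknown type tag {tag!r}")


def validate(tree: ParamTree, spec: ParamSpec, _prefix: str = "") -> ValidationReport:
    """Check a fully resolved tree against a :class:`ParamSpec`.

    An empty report (``report.ok``) means valid.  Unknown keys are reported
    (typo protection).
    """
    report = ValidationReport()
    _validate_into(tree, spec, _prefix, report)
    return report


def _validate_into(tree: ParamTree, spec: ParamSpec, prefix: str, report: ValidationReport) -> None:
    for name, tag in spec.entries.items():
        path = f"{prefix}{name}"
        if name not in tree:
            report.missing.append(path)
            continue
        value = tree[name]
        if isinstance(tag, ParamSpec):
            if not isinstance(value, ParamTree):
                report.type_mismatches.append(path)
            else:
                _validate_into(value, tag, path + ".", report)
        elif isinstance(value, (Reference, Expression)):
            report.type_mismatches.append(path)  # unresolved node
        elif not _type_ok(value, tag):
            report.type_mismatches.append(path)
    for name in tree:
        if name not in spec.entries:
            report.unknown.append(f"{prefix}{name}")


# ---------------------------------------------------------------------------
# Override / sampling / serialization
# ---------------------------------------------------------------------------

def override(tree: ParamTree, path: str, value: Any) -> ParamTree:
    """Return a copy of ``tree`` with the leaf at dotted ``path`` replaced."""
    out = tree.copy()
    try:
        out.set_path(path, value)
    except KeyError:
        raise ConfigError(f"override path does not exist: {path!r}") from None
    return out


def sample_distribution(spec: DistributionSpec, rng: np.random.Generator,
                        size: int | tuple | None = None):
    """Draw from a distribution literal; min == max yields the constant."""
    if spec.min == spec.max:
        if size is None:
            return spec.min
        return np.full(size, spec.min, dtype=float)
    return rng.uniform(spec.min, spec.max, size=size)


def _serialize_value(value: Any, indent: int) -> str:
    pad = "    " * (indent + 1)
    if isinstance(value, ParamTree):
        if len(value) == 0:
            return "{}"
        parts = [f"{pad}{k!r}: {_serialize_value(v, indent + 1)}" for k, v in value.items()]
        return "{\n" + ",\n".join(parts) + "\n" + "    " * indent + "}"
    if isinstance(value, DistributionSpec):
        return f"UniformDist(min={value.min!r}, max={value.max!r})"
    if isinstance(value, Reference):
        return f"ref({value.path!r})"
    if isinstance(value, Expression):
        if value.op == "neg":
            return f"-({_serialize_value(value.args[0], indent)})"
        left, right = (_serialize_value(a, indent) for a in value.args)
        return f"({left} {value.op} {right})"
    if isinstance(value, float) and (math.isinf(value) or math.isnan(value)):
        raise ConfigError("cannot serialize non-finite number")
    return repr(value)


def serialize_param_tree(tree: ParamTree) -> str:
    """Render a tree back to dialect text; ``parse_param_text`` inverts it."""
    return _serialize_value(tree, 0) + "\n"
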