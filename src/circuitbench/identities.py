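"""Parameterized identity objects for stimuli and analysis structures.

Every stimulus presentation and analysis product is tagged with an
:class:`Identity`: the kind (class) name plus an ordered set of declared
parameters, each with a type, units and optional periodicity.  Identities
round-trip exactly through a canonical string form, which is what the
datastore persists and what ``param_filter_query`` matches against.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "IdentityError",
    "ParamDecl",
    "Identity",
    "make_identity",
    "identity_to_string",
    "identity_from_string",
    "matches",
    "strip_params",
]

#: absolute tolerance for float criterion comparison
FLOAT_TOL = 1e-9


class IdentityError(ValueError):
    pass


@dataclass(frozen=True)
class ParamDecl:
    """Declaration of one identity parameter.

    ``period``, when present, must be positive; values of periodic
    parameters are stored reduced to ``[0, period)``.
    """

    name: str
    vtype: type = float
    units: str = "dimensionless"
    period: float | None = None
    doc: str = ""

    def __post_init__(self) -> None:
        if self.period is not None and not self.period > 0:
            raise IdentityError(f"parameter {self.name!r}: period must be > 0")


def _reduce(value: Any, decl: ParamDecl) -> Any:
    if decl.period is not None and isinstance(value, (int, float)):
        v = float(value) % decl.period
        # float modulo can return the period itself for tiny negatives
        if v >= decl.period:
            v -= decl.period
        return v
    return value


@dataclass(frozen=True, eq=False)
class Identity:
    """Kind name + declared parameters + values.

    Equality and hashing go through the canonical string (kind + sorted
    name=value pairs): two identities are the same identity iff they encode
    to the same string, regardless of declaration metadata such as units.
    """

    kind: str
    decls: tuple[ParamDecl, ...]
    values: tuple[tuple[str, Any], ...]  # sorted by name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Identity):
            return NotImplemented
        return identity_to_string(self) == identity_to_string(other)

    def __getitem__(self, name: str) -> Any:
        for k, v in self.values:
            if k == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(k == name for k, _ in self.values)

    def decl(self, name: str) -> ParamDecl:
        for d in self.decls:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.values)

    def as_dict(self) -> dict[str, Any]:
        return dict(self.values)

    def __str__(self) -> str:
        return identity_to_string(self)

    def __hash__(self) -> int:
        return hash(identity_to_string(self))


def make_identity(kind: str, decls: Sequence[ParamDecl], values: Mapping[str, Any]) -> Identity:
    """Build an identity; values must cover the declarations exactly."""
    declared = {d.name: d for d in decls}
    missing = sorted(set(declared) - set(values))
    extra = sorted(set(values) - set(declared))
    if missing:
        raise IdentityError(f"missing parameter(s): {', '.join(missing)}")
    if extra:
        raise IdentityError(f"undeclared parameter(s): {', '.join(extra)}")
    reduced = []
    for name in sorted(declared):
        decl = declared[name]
        value = values[name]
        if decl.vtype is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, decl.vtype):
            raise IdentityError(
                f"parameter {name!r}: expected {decl.vtype.__name__}, got {type(value).__name__}"
            )
        reduced.append((name, _reduce(value, decl)))
    return Identity(kind, tuple(decls), tuple(reduced))


# ---------------------------------------------------------------------------
# Canonical string form
# ---------------------------------------------------------------------------

def _format_value(value: Any) -> str:
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return repr(value)


_IDENTITY_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\((.*)\)\s*$", re.S)


def identity_to_string(identity: Identity) -> str:
    """Canonical ``Kind(name=value, ...)`` encoding with sorted names.

    Equal identities produce equal strings, so string equality is identity
    equality.
    """
    body = ", ".join(f"{k}={_format_value(v)}" for k, v in identity.values)
    return f"{identity.kind}({body})"


def identity_from_string(s: str) -> Identity:
    """Invert :func:`identity_to_string`.

    Declarations are reconstructed from the value types (units and periods
    are not encoded in the string; matching and grouping only need names,
    values and kinds, and periodic values are stored already reduced).
    """
    m = _IDENTITY_RE.match(s)
    if not m:
        raise IdentityError(f"malformed identity string: {s!r}")
    kind, body = m.group(1), m.group(2).strip()
    values: dict[str, Any] = {}
    if body:
        try:
            call = ast.parse(f"_f({body})", mode="eval").body
            assert isinstance(call, ast.Call)
            for kw in call.keywords:
                if kw.arg is None:
                    raise IdentityError(f"malformed identity string: {s!r}")
                values[kw.arg] = ast.literal_eval(kw.value)
        except (SyntaxError, ValueError) as exc:
            raise IdentityError(f"malformed identity string: {s!r}") from exc
    decls = tuple(ParamDecl(name, type(value)) for name, value in sorted(values.items()))
    return Identity(kind, decls, tuple(sorted(values.items())))


# ---------------------------------------------------------------------------
# Matching and grouping
# ---------------------------------------------------------------------------

def _value_matches(value: Any, wanted: Any, decl: ParamDecl | None) -> bool:
    period = decl.period if decl else None
    if isinstance(value, (int, float)) and isinstance(wanted, (int, float)) \
            and not isinstance(value, bool) and not isinstance(wanted, bool):
        if period is not None:
            diff = abs((float(value) - float(wanted)) % period)
            return min(diff, period - diff) <= FLOAT_TOL
        return abs(float(value) - float(wanted)) <= FLOAT_TOL
    return value == wanted


def matches(identity: Identity, criteria: Mapping[str, Any]) -> bool:
    """True iff every criterion is satisfied.

    A list criterion means membership (OR over the listed values); an
    undeclared parameter name excludes the identity.  Periodic parameters
    compare modulo their period with absolute tolerance ``1e-9``.
    """
    for name, wanted in criteria.items():
        if name not in identity:
            return False
        try:
            decl = identity.decl(name)
        except KeyError:
            decl = None
        value = identity[name]
        options = wanted if isinstance(wanted, (list, tuple)) else [wanted]
        if not any(_value_matches(value, opt, decl) for opt in options):
            return False
    return True


def strip_params(identity: Identity, names: Iterable[str]) -> Identity:
    """Remove the listed parameters (declaration and value) — the grouping
    key used for trial-averaging."""
    names = list(names)
    declared = {d.name for d in identity.decls}
    unknown = sorted(set(names) - declared)
    if unknown:
        raise IdentityError(f"cannot strip undeclared parameter(s): {', '.join(unknown)}")
    drop = set(names)
    return Identity(
        identity.kind,
        tuple(d for d in identity.decls if d.name not in drop),
        tuple((k, v) for k, v in identity.values if k not in drop),
    )
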