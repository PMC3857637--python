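"""Modular probabilistic connectors.

A modular connector builds one synaptic projection between two sheets.  Per
target neuron it evaluates a set of named connector functions over all
source neurons — a distance kernel, a push-pull (orientation/phase) kernel,
a Gabor afferent kernel, or a constant — combines them through an
arithmetic *weight expression* (e.g. ``'f1*f2'``), clips negatives, and
normalizes the result into a probability mass from which ``num_samples``
source neurons are drawn i.i.d. with replacement (multapses are kept as
separate synapses).  Every drawn synapse carries ``base_weight`` and a
delay given by the *delay expression* evaluated for that pair.

Kernels
-------
hyperbolic (lateral, distance d um):   exp(-alpha * sqrt(theta^2 + d^2))
push-pull (excitatory projections peak at matching orientation and phase,
inhibitory at matching orientation but opposite phase):
    exp(-d_pi(dor)^2 / (2 s_or^2)) * exp(-d_2pi(dph - phi0)^2 / (2 s_ph^2))
with circular distances and phi0 = 0 (excitatory) or pi (inhibitory).
Gabor afferent (LGN offset (dx, dy) deg from the target's RF centre):
    G = exp(-(a^2 + (ar*b)^2) / (2 size^2)) * cos(2 pi f a + phase)
with a across-stripe, b along-stripe coordinates; ON cells sample from
max(G, 0), OFF cells from max(-G, 0).
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .sheets import Sheet

__all__ = [
    "ConnectorError",
    "ConnectorFunctionSpec",
    "TMParams",
    "ModularConnectorSpec",
    "ConnectionList",
    "eval_expression",
    "hyperbolic_value",
    "pushpull_value",
    "gabor_value",
    "sample_connections",
]

#: smallest representable delay (the simulator step), ms
MIN_DELAY = 0.1


class ConnectorError(ValueError):
    pass


@dataclass(frozen=True)
class TMParams:
    """Tsodyks-Markram short-term plasticity parameters.

    ``U`` is the utilization parameter (the configuration key ``u``);
    ``tau_rec`` / ``tau_fac`` the recovery / facilitation time constants
    (ms); ``tau_psc`` the post-synaptic conductance decay used for STP
    synapses (ms).
    """

    U: float
    tau_rec: float
    tau_fac: float = 0.0
    tau_psc: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be > 0")


@dataclass(frozen=True)
class ConnectorFunctionSpec:
    """One named connector function; ``params`` depend on ``kind``.

    kinds: ``Hyperbolic`` (theta um, alpha 1/um), ``V1PushPull`` (or_sigma,
    phase_sigma rad), ``GaborAfferent`` (aspect_ratio, size deg, frequency
    cycles/deg, polarity 'ON'|'OFF'), ``Constant`` (value).
    """

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("Hyperbolic", "V1PushPull", "GaborAfferent", "Constant"):
            raise ConnectorError(f"unknown connector function kind {self.kind!r}")


@dataclass(frozen=True)
class ModularConnectorSpec:
    weight_functions: Mapping[str, ConnectorFunctionSpec]
    weight_expression: str
    base_weight: float                 # uS (cond) / nA (curr)
    num_samples: int
    target_synapses: str = "excitatory"
    delay_functions: Mapping[str, ConnectorFunctionSpec] = field(default_factory=dict)
    delay_expression: str = "2"
    short_term_plasticity: TMParams | None = None

    def __post_init__(self) -> None:
        if self.base_weight < 0:
            raise ConnectorError("base_weight must be >= 0")
        if self.num_samples < 0:
            raise ConnectorError("num_samples must be >= 0")
        if self.target_synapses not in ("excitatory", "inhibitory"):
            raise ConnectorError("target_synapses must be excitatory|inhibitory")


@dataclass
class ConnectionList:
    """Realized synapses of one projection (row-per-synapse arrays)."""

    source: np.ndarray          # source neuron index
    target: np.ndarray          # target neuron index
    weight: np.ndarray          # uS / nA
    delay: np.ndarray           # ms
    target_synapses: str = "excitatory"
    short_term_plasticity: TMParams | None = None
    source_sheet: str = ""
    target_sheet: str = ""

    def __len__(self) -> int:
        return self.source.shape[0]

    def to_tsv(self, path) -> None:
        """Tab-separated (source, target, weight_uS, delay_ms) export."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight_uS\tdelay_ms\n")
            for s, t, w, d in zip(self.source, self.target, self.weight, self.delay):
                fh.write(f"{int(s)}\t{int(t)}\t{float(w)!r}\t{float(d)!r}\n")


# ---------------------------------------------------------------------------
# Expression evaluation (restricted arithmetic over named arrays)
# ---------------------------------------------------------------------------

_BINOPS = {ast.Add: np.add, ast.Sub: np.subtract, ast.Mult: np.multiply,
           ast.Div: np.divide}


def _eval_node(node: ast.expr, bindings: Mapping[str, np.ndarray]):
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    if isinstance(node, ast.Name):
        if node.id not in bindings:
            raise ConnectorError(f"unknown name {node.id!r} in connector expression")
        return bindings[node.id]
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return -_eval_node(node.operand, bindings)
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        left = _eval_node(node.left, bindings)
        right = _eval_node(node.right, bindings)
        if type(node.op) is ast.Div and np.any(np.asarray(right) == 0):
            raise ConnectorError("division by zero in connector expression")
        return _BINOPS[type(node.op)](left, right)
    raise ConnectorError(f"unsupported syntax in connector expression")


def eval_expression(expr: str, bindings: Mapping[str, np.ndarray],
                    length: int | None = None) -> np.ndarray:
    """Evaluate an arithmetic expression elementwise over bound arrays.

    A bare numeral yields a constant array (``length`` or inferred from the
    bindings).
    """
    try:
        node = ast.parse(expr, mode="eval").body
    except SyntaxError as exc:
        raise ConnectorError(f"syntax error in expression {expr!r}: {exc.msg}") from exc
    result = _eval_node(node, bindings)
    if np.isscalar(result) or np.ndim(result) == 0:
        if length is None:
            length = len(next(iter(bindings.values()))) if bindings else 1
        return np.full(length, float(result))
    return np.asarray(result, dtype=float)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def hyperbolic_value(d, theta: float, alpha: float):
    """Distance kernel exp(-alpha * sqrt(theta^2 + d^2)); d in um."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ConnectorError("distance must be >= 0")
    return np.exp(-alpha * np.sqrt(theta * theta + d * d))


def _circ_dist(delta, period: float):
    delta = np.mod(np.asarray(delta, dtype=float), period)
    return np.minimum(delta, period - delta)


def pushpull_value(d_or, d_phase, or_sigma: float, phase_sigma: float,
                   synapse_type: str = "excitatory"):
    """Push-pull kernel over orientation difference (period pi) and phase
    difference (period 2 pi); inhibitory projections peak anti-phase."""
    phi0 = 0.0 if synapse_type == "excitatory" else math.pi
    a = _circ_dist(d_or, math.pi)
    b = _circ_dist(np.asarray(d_phase, dtype=float) - phi0, 2.0 * math.pi)
    return np.exp(-a * a / (2.0 * or_sigma ** 2)) * np.exp(-b * b / (2.0 * phase_sigma ** 2))


def gabor_value(dx, dy, orientation: float, phase: float, frequency: float,
                size: float, aspect_ratio: float, polarity: str | None = None):
    """Gabor receptive-field kernel; see the module docstring.

    ``polarity`` 'ON' returns max(G, 0), 'OFF' returns max(-G, 0), None
    returns the signed G.
    """
    if size <= 0:
        raise ConnectorError("gabor size must be > 0")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    a = -dx * math.sin(orientation) + dy * math.cos(orientation)   # across stripes
    b = dx * math.cos(orientation) + dy * math.sin(orientation)    # along stripes
    g = np.exp(-(a * a + (aspect_ratio * b) ** 2) / (2.0 * size ** 2)) \
        * np.cos(2.0 * math.pi * frequency * a + phase)
    if polarity is None:
        return g
    if polarity == "ON":
        return np.maximum(g, 0.0)
    if polarity == "OFF":
        return np.maximum(-g, 0.0)
    raise ConnectorError(f"unknown polarity {polarity!r}")


# ---------------------------------------------------------------------------
# Per-target evaluation and sampling
# ---------------------------------------------------------------------------

def _function_values(fn: ConnectorFunctionSpec, source: Sheet, target: Sheet,
                     tidx: int, synapse_type: str) -> np.ndarray:
    p = fn.params
    if fn.kind == "Constant":
        return np.full(source.size, float(p.get("value", 1.0)))
    if fn.kind == "Hyperbolic":
        d = np.linalg.norm(source.positions - target.positions[tidx], axis=1)
        return hyperbolic_value(d, float(p["theta"]), float(p["alpha"]))
    if fn.kind == "V1PushPull":
        for key in ("orientation", "phase"):
            if key not in source.metadata or key not in target.metadata:
                raise ConnectorError(
                    f"V1PushPull needs {key!r} metadata on both sheets"
                )
        d_or = source.metadata["orientation"] - target.metadata["orientation"][tidx]
        d_ph = source.metadata["phase"] - target.metadata["phase"][tidx]
        return pushpull_value(d_or, d_ph, float(p["or_sigma"]), float(p["phase_sigma"]),
                              synapse_type)
    if fn.kind == "GaborAfferent":
        sv = source.visual_positions()
        tv = target.visual_positions()[tidx]
        return gabor_value(
            sv[:, 0] - tv[0], sv[:, 1] - tv[1],
            float(target.metadata["orientation"][tidx]),
            float(target.metadata["phase"][tidx]),
            float(p["frequency"]), float(p["size"]), float(p["aspect_ratio"]),
            p.get("polarity"),
        )
    raise ConnectorError(f"unknown kind {fn.kind!r}")  # pragma: no cover


def sample_connections(spec: ModularConnectorSpec, source: Sheet, target: Sheet,
                       rng: np.random.Generator) -> ConnectionList:
    """Draw the projection: per target, ``num_samples`` sources i.i.d. from
    the normalized clipped weight-expression values."""
    sources, targets, delays = [], [], []
    for tidx in range(target.size):
        bindings = {
            name: _function_values(fn, source, target, tidx, spec.target_synapses)
            for name, fn in spec.weight_functions.items()
        }
        values = eval_expression(spec.weight_expression, bindings, length=source.size)
        values = np.clip(values, 0.0, None)
        total = values.sum()
        if total <= 0:
            raise ConnectorError(
                f"all-zero connection distribution for target neuron {tidx} "
                f"of sheet {target.name!r}"
            )
        drawn = rng.choice(source.size, size=spec.num_samples, replace=True,
                           p=values / total)
        delay_bindings = {
            name: _function_values(fn, source, target, tidx, spec.target_synapses)[drawn]
            for name, fn in spec.delay_functions.items()
        }
        dvals = eval_expression(spec.delay_expression, delay_bindings,
                                length=spec.num_samples)
        sources.append(drawn)
        targets.append(np.full(spec.num_samples, tidx))
        delays.append(np.maximum(dvals, MIN_DELAY))
    n_total = spec.num_samples * target.size
    return ConnectionList(
        source=np.concatenate(sources) if sources else np.empty(0, int),
        target=np.concatenate(targets) if targets else np.empty(0, int),
        weight=np.full(n_total, spec.base_weight),
        delay=np.concatenate(delays) if delays else np.empty(0),
        target_synapses=spec.target_synapses,
        short_term_plasticity=spec.short_term_plasticity,
        source_sheet=source.name,
        target_sheet=target.name,
    )
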