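"""Meta-workflow: grid parameter search, collation, benchmark network.

A combination search enumerates the cartesian product of the supplied
parameter value lists in deterministic (lexicographic) order, overrides
the base configuration at each dotted path, runs the workflow in a
per-combination run directory under a master directory, and records a
manifest.  Collation walks the run directories, filters each run's
datastore, and tabulates its ``SingleValue`` products against the varied
parameters; a grid figure shows each ``value_name`` as a heat map (2
varied parameters) or line (1 parameter), with axis labels carrying the
full parameter paths.

Execution backends: a local sequential backend, plus a cluster-submission
stub that records what it would submit (no scheduler in this release).
"""

from __future__ import annotations

import itertools
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np

from .config import ParamTree, override
from .connectors import ConnectionList
from .datastore import SingleValue, load, param_filter_query
from .sheets import BackgroundNoiseSpec, Sheet, SheetSpec
from .simulator import Network, NeuronModelParams
from .plotting import FigureTree, LineLeaf, MatrixLeaf, render

__all__ = [
    "SearchSpec",
    "SearchManifest",
    "LocalBackend",
    "StubClusterBackend",
    "combination_search",
    "collate_single_values",
    "single_value_grid_figure",
    "vogels_abbott_network",
    "network_in_degrees",
]

MANIFEST_NAME = "manifest.json"

#: a runner executes one configured model run inside its run directory
Runner = Callable[[ParamTree, Path], None]


class LocalBackend:
    """Sequential in-process execution."""

    name = "local"

    def execute(self, runner: Runner, config: ParamTree, run_dir: Path) -> None:
        runner(config, run_dir)


class StubClusterBackend:
    """Interface stand-in for a cluster scheduler: records the submission
    it would make instead of executing it."""

    name = "stub-cluster"

    def __init__(self) -> None:
        self.submitted: list[Path] = []

    def execute(self, runner: Runner, config: ParamTree, run_dir: Path) -> None:
        self.submitted.append(run_dir)
        (run_dir / "SUBMITTED").write_text("queued (stub backend)\n", encoding="utf-8")


@dataclass
class SearchSpec:
    base_config: ParamTree
    parameters: Mapping[str, Sequence[Any]]   # dotted path -> value list
    master_dir: str | Path
    runner: Runner
    backend: LocalBackend | StubClusterBackend = field(default_factory=LocalBackend)

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("a parameter search needs at least one parameter")
        for path in self.parameters:
            if not self.base_config.has_path(path):
                raise ValueError(f"search path not in base config: {path!r}")


@dataclass
class RunRecord:
    run_dir: str
    assignment: dict[str, Any]
    status: str   # "ok" | "failed" | "submitted"
    error: str = ""


@dataclass
class SearchManifest:
    master_dir: str
    runs: list[RunRecord] = field(default_factory=list)

    def save(self) -> None:
        path = Path(self.master_dir) / MANIFEST_NAME
        payload = {
            "runs": [
                {"run_dir": r.run_dir, "assignment": r.assignment,
                 "status": r.status, "error": r.error}
                for r in self.runs
            ],
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, master_dir: str | Path) -> "SearchManifest":
        path = Path(master_dir) / MANIFEST_NAME
        payload = json.loads(path.read_text(encoding="utf-8"))
        return cls(str(master_dir),
                   [RunRecord(**r) for r in payload["runs"]])


def _format_value(value: Any) -> str:
    return repr(value) if isinstance(value, float) else str(value)


def run_dir_name(assignment: Mapping[str, Any]) -> str:
    """``path=value`` pairs, sorted, comma-joined — unique and parseable."""
    return ",".join(f"{path}={_format_value(assignment[path])}"
                    for path in sorted(assignment))


def parse_run_dir_name(name: str) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for part in name.split(","):
        path, _, raw = part.partition("=")
        try:
            out[path] = int(raw)
        except ValueError:
            try:
                out[path] = float(raw)
            except ValueError:
                out[path] = raw
    return out


def combination_search(spec: SearchSpec) -> SearchManifest:
    """Run every combination; failures are recorded and the search
    continues."""
    master = Path(spec.master_dir)
    master.mkdir(parents=True, exist_ok=True)
    manifest = SearchManifest(str(master))
    paths = sorted(spec.parameters)
    for combo in itertools.product(*(spec.parameters[p] for p in paths)):
        assignment = dict(zip(paths, combo))
        config = spec.base_config
        for path, value in assignment.items():
            config = override(config, path, value)
        run_dir = master / run_dir_name(assignment)
        run_dir.mkdir(parents=True, exist_ok=True)
        try:
            spec.backend.execute(spec.runner, config, run_dir)
            status = ("submitted" if isinstance(spec.backend, StubClusterBackend)
                      else "ok")
            manifest.runs.append(RunRecord(run_dir.name, assignment, status))
        except Exception:
            manifest.runs.append(RunRecord(run_dir.name, assignment, "failed",
                                           traceback.format_exc(limit=3)))
    manifest.save()
    return manifest


def collate_single_values(master_dir: str | Path,
                          filter_criteria: Mapping[str, Any] | None = None,
                          store_subdir: str = "datastore") -> list[dict[str, Any]]:
    """Per run: the assignment plus ``{value_name: value}`` of every
    SingleValue surviving the filter; a run with no match gets an explicit
    ``values == {}`` gap entry."""
    manifest = SearchManifest.load(master_dir)
    table: list[dict[str, Any]] = []
    for run in manifest.runs:
        row: dict[str, Any] = {"assignment": dict(run.assignment), "values": {},
                               "status": run.status}
        store_dir = Path(master_dir) / run.run_dir / store_subdir
        if run.status == "ok":
            try:
                store = load(store_dir)
            except (FileNotFoundError, ValueError) as exc:
                raise RuntimeError(f"unreadable run store {store_dir}: {exc}") from exc
            view = store.full_view()
            if filter_criteria:
                view = param_filter_query(view, **filter_criteria)
            for ads in view.ads:
                if isinstance(ads, SingleValue):
                    row["values"][ads.value_name] = float(ads.value)
        table.append(row)
    return table


def single_value_grid_figure(table: Sequence[Mapping[str, Any]],
                             output_file: str | Path) -> FigureTree:
    """One panel per value_name over the 1- or 2-parameter grid."""
    if not table:
        raise ValueError("empty collation table")
    param_paths = sorted(table[0]["assignment"])
    if len(param_paths) > 2:
        raise ValueError("grid figures support at most 2 varied parameters; "
                         "slice the table first")
    value_names = sorted({name for row in table for name in row["values"]})
    if not value_names:
        raise ValueError("no SingleValue entries in the table")
    tree = FigureTree(1, len(value_names))
    if len(param_paths) == 2:
        px, py = param_paths
        xs = sorted({row["assignment"][px] for row in table})
        ys = sorted({row["assignment"][py] for row in table})
        for col, vname in enumerate(value_names):
            matrix = np.full((len(ys), len(xs)), np.nan)
            for row in table:
                i = ys.index(row["assignment"][py])
                j = xs.index(row["assignment"][px])
                if vname in row["values"]:
                    matrix[i, j] = row["values"][vname]
            tree.add(0, col, MatrixLeaf(matrix=matrix, x_values=xs, y_values=ys,
                                        x_label=px, y_label=py, title=vname))
    else:
        px = param_paths[0]
        for col, vname in enumerate(value_names):
            pts = sorted(
                (row["assignment"][px], row["values"][vname])
                for row in table if vname in row["values"]
            )
            x = np.array([p[0] for p in pts], dtype=float)
            y = np.array([p[1] for p in pts], dtype=float)
            leaf = LineLeaf(time=x, mean_traces=[(y, "tab:blue")],
                            ylabel=vname, title=vname)
            tree.add(0, col, leaf)
    render(tree, output_file, figsize=(5.5 * len(value_names), 4.5))
    return tree


# ---------------------------------------------------------------------------
# Vogels-Abbott benchmark network
# ---------------------------------------------------------------------------

def vogels_abbott_network(n_neurons: int, target_in_degree: float,
                          rng: np.random.Generator,
                          model_params: NeuronModelParams | None = None,
                          exc_weight: float = 0.004, inh_weight: float = 0.051,
                          delay: float = 2.0) -> Network:
    """Sparsely coupled conductance-based benchmark network.

    80% excitatory / 20% inhibitory neurons; every ordered pair (no
    self-connections) is connected independently with probability
    ``target_in_degree / n_neurons``, so the mean in-degree is
    ``(n_neurons - 1) * p`` — within a fraction of a synapse of the target.
    Default weights (uS) follow the standard sparse conductance variant.
    """
    if n_neurons < 10:
        raise ValueError("need at least 10 neurons")
    if target_in_degree >= n_neurons:
        raise ValueError("target in-degree must be below the population size")
    p = target_in_degree / n_neurons
    n_exc = int(round(0.8 * n_neurons))
    n_inh = n_neurons - n_exc
    if model_params is None:
        model_params = NeuronModelParams(
            model="IF_cond_exp", v_rest=-60.0, v_reset=-60.0, v_thresh=-50.0,
            tau_m=20.0, cm=0.2, tau_refrac=5.0, tau_syn_E=5.0, tau_syn_I=10.0,
            e_rev_E=0.0, e_rev_I=-80.0,
        )
    network = Network()
    sizes = {"Exc": n_exc, "Inh": n_inh}
    for label, size in sizes.items():
        spec = SheetSpec(
            name=label, sx=1000.0, sy=1000.0, density=size,  # 1 mm^2 footprint
            magnification_factor=1000.0,
            cell_model=model_params.model,
            background_noise=BackgroundNoiseSpec(),
        )
        positions = np.column_stack([
            rng.uniform(-500.0, 500.0, size=size),
            rng.uniform(-500.0, 500.0, size=size),
        ])
        network.add_sheet(Sheet(spec, positions), model_params)

    for src_label, n_src in sizes.items():
        weight = exc_weight if src_label == "Exc" else inh_weight
        synapse = "excitatory" if src_label == "Exc" else "inhibitory"
        for tgt_label, n_tgt in sizes.items():
            sources, targets = [], []
            same = src_label == tgt_label
            for tgt in range(n_tgt):
                n_candidates = n_src - 1 if same else n_src
                k = rng.binomial(n_candidates, p)
                if k == 0:
                    continue
                pool = np.delete(np.arange(n_src), tgt) if same else np.arange(n_src)
                drawn = rng.choice(pool, size=k, replace=False)
                sources.append(drawn)
                targets.append(np.full(k, tgt))
            n_edges = sum(len(s) for s in sources)
            conn = ConnectionList(
                source=np.concatenate(sources) if sources else np.empty(0, int),
                target=np.concatenate(targets) if targets else np.empty(0, int),
                weight=np.full(n_edges, weight),
                delay=np.full(n_edges, delay),
                target_synapses=synapse,
                source_sheet=src_label,
                target_sheet=tgt_label,
            )
            network.add_projection(conn)
    return network


def network_in_degrees(network: Network) -> np.ndarray:
    """Realized in-degree of every neuron over all projections."""
    sizes = {name: sheet.size for name, sheet in network.sheets.items()}
    order = list(network.sheets)
    offsets = {}
    total = 0
    for name in order:
        offsets[name] = total
        total += sizes[name]
    degrees = np.zeros(total, dtype=int)
    for conn in network.connections:
        np.add.at(degrees, conn.target.astype(int) + offsets[conn.target_sheet], 1)
    return degrees
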