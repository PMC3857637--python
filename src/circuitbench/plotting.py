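"""Hierarchical figure trees.

A figure is a tree: inner nodes partition their region of the figure into
a grid (via matplotlib GridSpec) and place children into cells; leaves
draw exactly one axes each.  Leaf kinds: spike raster, line plot (analog
traces), tuning curve, and parameter-grid matrix.  Labels and units are
drawn from the metadata the datastore carries, so plots annotate
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .datastore import DataStore, DataStoreView, param_filter_query, partition_by_stimulus
from .analysis import tuning_curves as _tuning_curves  # noqa: E402
from .identities import identity_to_string, strip_params  # noqa: E402

__all__ = [
    "Leaf",
    "RasterLeaf",
    "LineLeaf",
    "TuningCurveLeaf",
    "MatrixLeaf",
    "FigureTree",
    "render",
    "overview_plot",
    "tuning_curve_plot",
]


class Leaf:
    """Base leaf: draws into one axes."""

    title: str = ""

    def draw(self, ax: plt.Axes) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class RasterLeaf(Leaf):
    """Spike raster: one row per trial."""

    trains: Sequence[np.ndarray] = ()
    t_stop: float = 0.0
    title: str = ""

    def draw(self, ax: plt.Axes) -> None:
        for row, train in enumerate(self.trains):
            ax.vlines(np.asarray(train), row + 0.6, row + 1.4, color="k", lw=0.6)
        ax.set_ylim(0.5, max(len(self.trains), 1) + 0.5)
        if self.t_stop > 0:
            ax.set_xlim(0, self.t_stop)
        ax.set_ylabel("trial")
        ax.set_xlabel("time (ms)")
        if self.title:
            ax.set_title(self.title)


@dataclass
class LineLeaf(Leaf):
    """Analog traces: pale per-trial lines + saturated averages."""

    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_traces: Sequence[tuple[np.ndarray, str]] = ()   # (trace, color)
    mean_traces: Sequence[tuple[np.ndarray, str]] = ()
    ylabel: str = ""
    title: str = ""

    def draw(self, ax: plt.Axes) -> None:
        for trace, color in self.trial_traces:
            ax.plot(self.time, trace, color=color, alpha=0.3, lw=0.6)
        for trace, color in self.mean_traces:
            ax.plot(self.time, trace, color=color, lw=1.4)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel(self.ylabel)
        if self.title:
            ax.set_title(self.title)


@dataclass
class TuningCurveLeaf(Leaf):
    """Response value vs one stimulus parameter, one line per neuron."""

    curves: Sequence[tuple[np.ndarray, np.ndarray, str]] = ()  # (x, y, label)
    parameter_name: str = ""
    value_name: str = ""
    units: str = ""
    title: str = ""

    def draw(self, ax: plt.Axes) -> None:
        for x, y, label in self.curves:
            ax.plot(x, y, marker="o", label=label)
        ax.set_xlabel(self.parameter_name)
        ylabel = self.value_name + (f" ({self.units})" if self.units else "")
        ax.set_ylabel(ylabel)
        if len(self.curves) > 1:
            ax.legend(fontsize="x-small")
        if self.title:
            ax.set_title(self.title)


@dataclass
class MatrixLeaf(Leaf):
    """2D parameter-grid heat map with full-path axis labels."""

    matrix: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    x_values: Sequence[float] = ()
    y_values: Sequence[float] = ()
    x_label: str = ""
    y_label: str = ""
    title: str = ""

    def draw(self, ax: plt.Axes) -> None:
        masked = np.ma.masked_invalid(np.asarray(self.matrix, dtype=float))
        im = ax.imshow(masked, origin="lower", aspect="auto")
        ax.set_xticks(range(len(self.x_values)))
        ax.set_xticklabels([f"{v:g}" for v in self.x_values], fontsize="x-small")
        ax.set_yticks(range(len(self.y_values)))
        ax.set_yticklabels([f"{v:g}" for v in self.y_values], fontsize="x-small")
        ax.set_xlabel(self.x_label, fontsize="small")
        ax.set_ylabel(self.y_label, fontsize="small")
        plt.colorbar(im, ax=ax, shrink=0.8)
        if self.title:
            ax.set_title(self.title)


@dataclass
class FigureTree:
    """Inner node: an (nrows, ncols) grid of children.

    ``children`` maps (row, col, rowspan, colspan) cells to a child
    FigureTree or Leaf; cells must not overlap.
    """

    nrows: int
    ncols: int
    children: dict[tuple[int, int, int, int], "FigureTree | Leaf"] = field(
        default_factory=dict
    )
    title: str = ""

    def add(self, row: int, col: int, child: "FigureTree | Leaf",
            rowspan: int = 1, colspan: int = 1) -> None:
        cell = (row, col, rowspan, colspan)
        self._check_fit(cell)
        self.children[cell] = child

    def _check_fit(self, cell: tuple[int, int, int, int]) -> None:
        row, col, rs, cs = cell
        if row < 0 or col < 0 or row + rs > self.nrows or col + cs > self.ncols:
            raise ValueError(f"cell {cell} exceeds the {self.nrows}x{self.ncols} grid")
        new = {(r, c) for r in range(row, row + rs) for c in range(col, col + cs)}
        for (orow, ocol, ors, ocs) in self.children:
            old = {(r, c) for r in range(orow, orow + ors) for c in range(ocol, ocol + ocs)}
            if new & old:
                raise ValueError(f"cell {cell} overlaps an existing child")

    def leaf_count(self) -> int:
        return sum(child.leaf_count() if isinstance(child, FigureTree) else 1
                   for child in self.children.values())


def _render_into(node: FigureTree, fig: plt.Figure, subspec) -> None:
    gs = subspec.subgridspec(node.nrows, node.ncols) if subspec is not None \
        else fig.add_gridspec(node.nrows, node.ncols)
    for (row, col, rs, cs), child in node.children.items():
        cell = gs[row:row + rs, col:col + cs]
        if isinstance(child, FigureTree):
            _render_into(child, fig, cell)
        else:
            ax = fig.add_subplot(cell)
            child.draw(ax)


def render(tree: FigureTree, path: str | Path, format: str | None = None,
           figsize: tuple[float, float] = (10, 8)) -> Path:
    """Render a figure tree to file; the file's axes count equals the
    tree's leaf count."""
    fig = plt.figure(figsize=figsize)
    _render_into(tree, fig, None)
    if tree.title:
        fig.suptitle(tree.title)
    path = Path(path)
    fig.savefig(path, format=format, dpi=100)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Canned figures
# ---------------------------------------------------------------------------

def overview_plot(dsv: DataStore | DataStoreView, sheet_name: str, neuron: int,
                  path: str | Path | None = None) -> FigureTree:
    """Raw-response overview: one column per stimulus (stripped of trial);
    rows are spike raster over trials, conductances (exc red / inh blue),
    and membrane potential (grey trials, black average)."""
    view = dsv.full_view() if isinstance(dsv, DataStore) else dsv
    view = param_filter_query(view, sheet_name=sheet_name)
    groups = partition_by_stimulus(view, except_params=["trial"])
    if not groups:
        raise ValueError(f"no segments for sheet {sheet_name!r}")
    tree = FigureTree(1, len(groups))
    for col, group in enumerate(groups):
        segs = group.segments
        first = segs[0]
        if neuron not in set(int(i) for i in first.spike_ids) \
                and neuron not in set(int(i) for i in first.analog_ids):
            raise ValueError(f"neuron {neuron} not recorded in sheet {sheet_name!r}")
        stripped = identity_to_string(
            strip_params(first.stimulus, ["trial"])
            if "trial" in first.stimulus else first.stimulus
        )
        column = FigureTree(3, 1, title="")
        column.add(0, 0, RasterLeaf(
            trains=[seg.spike_train(neuron) for seg in segs],
            t_stop=first.duration,
            title=_short_title(stripped),
        ))
        t = np.arange(next(iter(first.analog.values())).shape[0]) * first.record_period \
            if first.analog else np.empty(0)
        gsyn_trials, gsyn_means = [], []
        for var, color in (("gsyn_exc", "red"), ("gsyn_inh", "blue")):
            traces = _neuron_traces(segs, neuron, var)
            gsyn_trials.extend((tr, color) for tr in traces)
            if traces:
                gsyn_means.append((np.mean(traces, axis=0), color))
        column.add(1, 0, LineLeaf(time=t, trial_traces=gsyn_trials,
                                  mean_traces=gsyn_means, ylabel="gsyn (uS)"))
        v_traces = _neuron_traces(segs, neuron, "v")
        column.add(2, 0, LineLeaf(
            time=t,
            trial_traces=[(tr, "grey") for tr in v_traces],
            mean_traces=[(np.mean(v_traces, axis=0), "black")] if v_traces else [],
            ylabel="Vm (mV)",
        ))
        tree.add(0, col, column)
    if path is not None:
        render(tree, path, figsize=(4 * len(groups), 8))
    return tree


def _short_title(identity_string: str) -> str:
    return identity_string if len(identity_string) <= 60 else identity_string[:57] + "..."


def _neuron_traces(segs, neuron: int, var: str) -> list[np.ndarray]:
    out = []
    for seg in segs:
        if var in seg.analog:
            idx = np.flatnonzero(seg.analog_ids == neuron)
            if idx.size:
                out.append(seg.analog[var][:, idx[0]])
    return out


def tuning_curve_plot(dsv: DataStore | DataStoreView, parameter_name: str,
                      neurons: Sequence[int],
                      path: str | Path | None = None) -> FigureTree:
    """One tuning-curve panel per residual stimulus-parameter combination."""
    curves = _tuning_curves(dsv, parameter_name, neurons)
    residual_keys = sorted({key for per_neuron in curves.values() for key in per_neuron})
    if not residual_keys:
        raise ValueError("no tuning data to plot")
    # take value_name/units off the first matching ADS
    view = dsv.full_view() if isinstance(dsv, DataStore) else dsv
    value_name, units = "", ""
    for ads in view.ads:
        if getattr(ads, "value_name", None):
            value_name, units = ads.value_name, ads.units
            break
    tree = FigureTree(1, len(residual_keys))
    for col, key in enumerate(residual_keys):
        leaf_curves = []
        for neuron, per_neuron in curves.items():
            if key in per_neuron:
                x, y = per_neuron[key]
                leaf_curves.append((x, y, f"neuron {neuron}"))
        tree.add(0, col, TuningCurveLeaf(
            curves=leaf_curves, parameter_name=parameter_name,
            value_name=value_name, units=units, title=_short_title(key),
        ))
    if path is not None:
        render(tree, path, figsize=(5 * len(residual_keys), 4))
    return tree
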