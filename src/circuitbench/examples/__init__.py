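"""Packaged example configuration for the push-pull cortical model.

``top.param`` plus its ``param/`` includes describe the full-scale model
(5 x 5 mm cortical sheets, 6.8 degree visual field).  Because a model run
writes next to its configuration (the generated orientation map), configs
are *materialized* — copied into a working directory — before use.
``desk_scale_tree`` shrinks the model to a few hundred neurons for quick
end-to-end runs.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

from ..config import ParamSpec, ParamTree, load_param_tree, override, resolve_references

__all__ = [
    "materialize_example",
    "load_example_tree",
    "desk_scale_tree",
    "push_pull_required_parameters",
]


def materialize_example(dest_dir: str | Path) -> Path:
    """Copy the example config family into ``dest_dir``; returns the path
    of the top-level file."""
    dest_dir = Path(dest_dir)
    (dest_dir / "param").mkdir(parents=True, exist_ok=True)
    pkg = resources.files(__package__)
    for entry in ("top.param",):
        (dest_dir / entry).write_text(
            (pkg / entry).read_text(encoding="utf-8"), encoding="utf-8")
    for entry in (pkg / "param").iterdir():
        if entry.name.endswith(".param"):
            shutil.copyfile(str(entry), dest_dir / "param" / entry.name)
    return dest_dir / "top.param"


def load_example_tree(dest_dir: str | Path) -> ParamTree:
    """Materialize (if needed), load and resolve the example config."""
    top = Path(dest_dir) / "top.param"
    if not top.exists():
        top = materialize_example(dest_dir)
    return resolve_references(load_param_tree(top))


def desk_scale_tree(tree: ParamTree) -> ParamTree:
    """Shrink the resolved example to a ~200-neuron model on a 3 degree
    field for fast end-to-end experiments."""
    changes = {
        "visual_field.size": (3.0, 3.0),
        "l4_cortex_exc.params.sx": 1000.0,
        "l4_cortex_exc.params.sy": 1000.0,
        "l4_cortex_exc.params.density": 160.0,
        "l4_cortex_exc.params.magnification_factor": 1000.0,
        "l4_cortex_exc.params.recorders.Spikes.params.num_of_cells": 50,
        "l4_cortex_exc.params.recorders.DetailedRecordings.params.num_of_cells": 5,
        "l4_cortex_exc.AfferentConnection.specific_arborization.num_samples": 40,
        "l4_cortex_inh.params.sx": 1000.0,
        "l4_cortex_inh.params.sy": 1000.0,
        "l4_cortex_inh.params.density": 40.0,
        "l4_cortex_inh.params.magnification_factor": 1000.0,
        "l4_cortex_inh.params.recorders.Spikes.params.num_of_cells": 20,
        "l4_cortex_inh.params.recorders.DetailedRecordings.params.num_of_cells": 3,
        "l4_cortex_inh.AfferentConnection.specific_arborization.num_samples": 40,
        "retina_lgn.params.recorders.Spikes.params.num_of_cells": 20,
    }
    for path, value in changes.items():
        tree = override(tree, path, value)
    return tree


def _sheet_block_spec(connection_names: tuple[str, ...]) -> ParamSpec:
    block = {
        "component": "string",
        "params": ParamSpec({
            "name": "string",
            "sx": "number",
            "sy": "number",
            "density": "number",
            "magnification_factor": "number",
            "cell": "any",
            "background_noise": ParamSpec({
                "exc_firing_rate": "number",
                "exc_weight": "number",
                "inh_firing_rate": "number",
                "inh_weight": "number",
            }),
            "recorders": "any",
        }),
        "AfferentConnection": "any",
    }
    for name in connection_names:
        block[name] = "any"
    return ParamSpec(block)


def push_pull_required_parameters() -> ParamSpec:
    """The required-parameter declaration of the push-pull model."""
    return ParamSpec({
        "input_space_type": "string",
        "input_space": ParamSpec({
            "update_interval": "number",
            "background_luminance": "number",
        }),
        "retina_lgn": "any",
        "l4_cortex_exc": _sheet_block_spec(
            ("L4ExcL4ExcConnection", "L4ExcL4InhConnection")),
        "l4_cortex_inh": _sheet_block_spec(
            ("L4InhL4ExcConnection", "L4InhL4InhConnection")),
        "visual_field": ParamSpec({"centre": "tuple", "size": "tuple"}),
        "results_dir": "string",
        "name": "string",
        "reset": "boolean",
        "null_stimulus_period": "number",
    })
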