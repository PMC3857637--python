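"""Model assembly: from a configuration tree to a runnable network.

``build_push_pull_model`` constructs the reference architecture: two LGN
mosaics (ON / OFF) feeding a cortical excitatory and a cortical inhibitory
sheet through Gabor-shaped afferent projections whose orientation and
phase preferences come from an orientation map, with push-pull lateral
connectivity within and between the cortical sheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .config import DistributionSpec, ParamTree
from .connectors import (
    ConnectorFunctionSpec,
    ModularConnectorSpec,
    TMParams,
    sample_connections,
)
from .retina import RetinaLGNSpec, build_lgn_mosaic, lgn_spike_trains
from .sheets import (
    BackgroundNoiseSpec,
    RecorderSpec,
    Sheet,
    SheetSpec,
    assign_orientation_map,
    build_sheet,
    generate_orientation_map,
    read_orientation_map,
    write_orientation_map,
)
from .simulator import Network, SimulationEngine
from .stimuli import StimulusDescriptor, VisualSpaceSpec, frames_for_stimulus
from .simulator import RecordedSegment

__all__ = ["Model", "build_push_pull_model", "present_stimulus", "blank_input_spikes"]


@dataclass
class Model:
    """A built network plus its sensory front-end."""

    name: str
    network: Network
    space: VisualSpaceSpec
    retina: RetinaLGNSpec | None = None
    input_sheets: tuple[str, ...] = ()
    config: ParamTree | None = None

    def engine(self, rng: np.random.Generator) -> SimulationEngine:
        return SimulationEngine(self.network, rng)


def _recorders_from_tree(tree: ParamTree | None) -> dict[str, RecorderSpec]:
    out: dict[str, RecorderSpec] = {}
    if tree is None:
        return out
    for label, block in tree.items():
        out[label] = RecorderSpec(
            selector=str(block.get_path("component")).rsplit(".", 1)[-1],
            num_of_cells=int(block.get_path("params.num_of_cells")),
            variables=tuple(block.get_path("variables")),
        )
    return out


def _sheet_spec_from_tree(tree: ParamTree) -> SheetSpec:
    p = tree["params"]
    noise = p["background_noise"]
    cell = p["cell"]
    initial = {}
    if "initial_values" in cell:
        for key, dist in cell["initial_values"].items():
            if isinstance(dist, DistributionSpec):
                initial[key] = dist
    return SheetSpec(
        name=str(p["name"]),
        sx=float(p["sx"]), sy=float(p["sy"]),
        density=float(p["density"]),
        magnification_factor=float(p["magnification_factor"]),
        cell_model=str(cell["model"]),
        cell_params={k: v for k, v in cell["params"].items()
                     if isinstance(v, (int, float)) and not isinstance(v, bool)},
        initial_values=initial,
        background_noise=BackgroundNoiseSpec(
            exc_firing_rate=float(noise["exc_firing_rate"]),
            exc_weight=float(noise["exc_weight"]),
            inh_firing_rate=float(noise["inh_firing_rate"]),
            inh_weight=float(noise["inh_weight"]),
        ),
        recorders=_recorders_from_tree(p.get_path("recorders") if "recorders" in p else None),
    )


_FUNCTION_KINDS = {
    "V1PushPullArborization": "V1PushPull",
    "HyperbolicConnectorFunction": "Hyperbolic",
    "GaborArborization": "GaborAfferent",
    "ConstantConnectorFunction": "Constant",
}


def _function_spec_from_tree(tree: ParamTree) -> ConnectorFunctionSpec:
    component = str(tree["component"]).rsplit(".", 1)[-1]
    if component not in _FUNCTION_KINDS:
        raise ValueError(f"unknown connector function component {component!r}")
    params = tree["params"].to_dict() if "params" in tree else {}
    return ConnectorFunctionSpec(_FUNCTION_KINDS[component], params)


def _stp_from_tree(tree: ParamTree | None) -> TMParams | None:
    if tree is None or len(tree) == 0:
        return None
    return TMParams(
        U=float(tree["u"]),
        tau_rec=float(tree["tau_rec"]),
        tau_fac=float(tree.get_path("tau_fac")) if "tau_fac" in tree else 0.0,
        tau_psc=float(tree.get_path("tau_psc")) if "tau_psc" in tree else 1.5,
    )


def connector_spec_from_tree(tree: ParamTree) -> ModularConnectorSpec:
    """A lateral-connection block (e.g. ``L4ExcL4ExcConnection``) to a
    :class:`ModularConnectorSpec`."""
    return ModularConnectorSpec(
        weight_functions={name: _function_spec_from_tree(fn)
                          for name, fn in tree["weight_functions"].items()},
        delay_functions={name: _function_spec_from_tree(fn)
                         for name, fn in tree["delay_functions"].items()}
        if "delay_functions" in tree else {},
        weight_expression=str(tree["weight_expression"]),
        delay_expression=str(tree["delay_expression"]),
        base_weight=float(tree["base_weight"]),
        num_samples=int(tree["num_samples"]),
        target_synapses=str(tree["target_synapses"]),
        short_term_plasticity=_stp_from_tree(
            tree["short_term_plasticity"] if "short_term_plasticity" in tree else None
        ),
    )


def _scalar_from_dist(value) -> float:
    if isinstance(value, DistributionSpec):
        if value.min != value.max:
            raise ValueError("per-target distribution parameters must be degenerate "
                             "(min == max) in this release")
        return value.min
    return float(value)


def _afferent_specs(tree: ParamTree, num_samples: int) -> dict[str, ModularConnectorSpec]:
    """ON and OFF Gabor projections from the ``AfferentConnection`` block;
    ``num_samples`` is split evenly between the polarities."""
    arbor = tree["specific_arborization"]
    base_weight = float(arbor["weight_factor"])
    stp = _stp_from_tree(arbor["short_term_plasticity"]
                         if "short_term_plasticity" in arbor else None)
    gabor_common = {
        "aspect_ratio": _scalar_from_dist(tree["aspect_ratio"]),
        "size": _scalar_from_dist(tree["size"]),
        "frequency": _scalar_from_dist(tree["frequency"]),
    }
    n_on = num_samples // 2
    specs = {}
    for polarity, n in (("ON", n_on), ("OFF", num_samples - n_on)):
        specs[polarity] = ModularConnectorSpec(
            weight_functions={"f1": ConnectorFunctionSpec(
                "GaborAfferent", {**gabor_common, "polarity": polarity})},
            weight_expression="f1",
            delay_expression=str(arbor.get_path("delay")) if "delay" in arbor else "2",
            base_weight=base_weight,
            num_samples=n,
            target_synapses=str(arbor["target_synapses"]),
            short_term_plasticity=stp,
        )
    return specs


def _retina_spec_from_tree(tree: ParamTree) -> RetinaLGNSpec:
    p = tree["params"]
    kwargs = {}
    mapping = {
        "sigma_c": "sigma_c", "sigma_s": "sigma_s", "A_c": "A_c", "A_s": "A_s",
        "tau_lgn": "tau_lgn", "baseline_rate": "r0", "gain": "gain",
        "max_rate": "r_max", "density": "density",
    }
    for key, attr in mapping.items():
        if key in p:
            kwargs[attr] = float(p[key])
    recorders = _recorders_from_tree(p.get_path("recorders") if "recorders" in p else None)
    return RetinaLGNSpec(recorders=recorders, **kwargs)


def _orientation_map(location: str, base_dir: Path, rng: np.random.Generator,
                     space: VisualSpaceSpec):
    """Read the map at ``location`` (relative to the config); generate and
    persist a synthetic one if the file does not exist yet."""
    path = (base_dir / location).resolve()
    if path.exists():
        return read_orientation_map(path)
    n = 96
    extent = max(space.size) * 1.2
    ormap = generate_orientation_map(
        n, spatial_period=extent / 6.0, k_components=40, rng=rng,
        deg_per_cell=extent / (n - 1),
    )
    write_orientation_map(ormap, path)
    return ormap


def build_push_pull_model(config: ParamTree, rng: np.random.Generator,
                          base_dir: str | Path = ".",
                          name: str | None = None) -> Model:
    """Assemble the push-pull cortical model from a resolved config tree."""
    base_dir = Path(base_dir)
    space_block = config["input_space"]
    field_block = config["visual_field"]
    space = VisualSpaceSpec(
        update_interval=float(space_block["update_interval"]),
        background_luminance=float(space_block["background_luminance"]),
        centre=tuple(field_block["centre"]),
        size=tuple(field_block["size"]),
    )
    retina = _retina_spec_from_tree(config["retina_lgn"])
    network = Network()
    mosaics = {}
    for polarity in ("ON", "OFF"):
        mosaic = build_lgn_mosaic(retina, space, polarity)
        mosaics[polarity] = mosaic
        network.add_sheet(mosaic)
    # mirror mosaics: OFF shares ON positions exactly
    mosaics["OFF"].positions = mosaics["ON"].positions.copy()

    cortex_sheets: dict[str, Sheet] = {}
    blocks: dict[str, ParamTree] = {}
    for key in ("l4_cortex_exc", "l4_cortex_inh"):
        block = config[key]
        sheet_spec = _sheet_spec_from_tree(block)
        sheet = build_sheet(sheet_spec, rng)
        cortex_sheets[key] = sheet
        blocks[key] = block
        network.add_sheet(sheet)

    # orientation map + phase assignment (shared across cortical sheets)
    aff = blocks["l4_cortex_exc"]["AfferentConnection"]
    ormap = _orientation_map(str(aff["or_map_location"]), base_dir, rng, space)
    phase_dist = aff["phase"] if isinstance(aff["phase"], DistributionSpec) else None
    for sheet in cortex_sheets.values():
        assign_orientation_map(sheet, ormap, phase_dist, rng)

    # afferent projections
    for key, sheet in cortex_sheets.items():
        aff_block = blocks[key]["AfferentConnection"]
        specs = _afferent_specs(aff_block,
                                int(aff_block["specific_arborization"]["num_samples"]))
        for polarity, spec in specs.items():
            conn = sample_connections(spec, mosaics[polarity], sheet, rng)
            network.add_projection(conn)

    # lateral projections: every *Connection block except AfferentConnection
    targets_by_suffix = {"Exc": "l4_cortex_exc", "Inh": "l4_cortex_inh"}
    for key, block in blocks.items():
        for conn_name in block:
            if not conn_name.endswith("Connection") or conn_name == "AfferentConnection":
                continue
            spec = connector_spec_from_tree(block[conn_name])
            # names follow L4<Src><...>L4<Tgt>Connection
            tgt_key = None
            for suffix, sheet_key in targets_by_suffix.items():
                if conn_name.endswith(f"L4{suffix}Connection"):
                    tgt_key = sheet_key
            if tgt_key is None:
                raise ValueError(f"cannot infer target sheet of {conn_name!r}")
            conn = sample_connections(spec, cortex_sheets[key],
                                      cortex_sheets[tgt_key], rng)
            network.add_projection(conn)

    network.select_recorders(rng)
    return Model(
        name=name or str(config["name"]) if "name" in config else "model",
        network=network,
        space=space,
        retina=retina,
        input_sheets=("X_ON", "X_OFF"),
        config=config,
    )


def present_stimulus(model: Model, stim: StimulusDescriptor,
                     engine: SimulationEngine,
                     rng: np.random.Generator) -> list[RecordedSegment]:
    """Render the stimulus, drive the LGN front-end, simulate, record."""
    frames = frames_for_stimulus(stim, model.space)
    input_spikes = {}
    if model.retina is not None:
        for polarity in ("ON", "OFF"):
            name = f"X_{polarity}"
            if name in model.network.sheets:
                input_spikes[name] = lgn_spike_trains(
                    frames, model.retina, model.space,
                    model.network.sheets[name], polarity, stim.duration, rng,
                )
    return engine.run(input_spikes, stim.duration, rng, stimulus=stim.identity())


def blank_input_spikes(model: Model, duration: float,
                       rng: np.random.Generator) -> dict[str, list[np.ndarray]]:
    """Baseline (r0) Poisson trains for the LGN mosaics over a blank."""
    out = {}
    if model.retina is None:
        return out
    from .retina import poisson_spikes

    n_frames = max(int(np.ceil(duration / model.space.update_interval)), 1)
    for polarity in ("ON", "OFF"):
        name = f"X_{polarity}"
        if name in model.network.sheets:
            n = model.network.sheets[name].size
            rates = np.full((n, n_frames), model.retina.r0)
            out[name] = poisson_spikes(rates, model.space.update_interval,
                                       duration, rng)
    return out
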