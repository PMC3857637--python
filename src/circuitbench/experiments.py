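"""Experiment protocols and the single-command workflow orchestration.

An experiment is a declarative list of stimuli.  The controller enumerates
each experiment's stimuli, removes any already recorded in the datastore
(deduplication), presents the rest one by one — separating presentations
with a blank of ``null_stimulus_period`` ms or a state reset so responses
are independent of presentation order — records segments into the store,
logs progress, and saves the store at the end.  Analyses can then be
re-run on the saved store without re-executing any simulation.
"""

from __future__ import annotations

import hashlib
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .datastore import DataStore, DataStoreView, load, save
from .identities import identity_to_string
from .model import Model, blank_input_spikes, present_stimulus
from .simulator import inter_presentation
from .stimuli import (
    FULLFIELD_GRATING,
    GRATING_DISK,
    NULL,
    StimulusDescriptor,
)

__all__ = [
    "MeasureSpontaneousActivity",
    "MeasureOrientationTuningFullfield",
    "MeasureSizeTuning",
    "WorkflowConfig",
    "enumerate_stimuli",
    "dedup_stimuli",
    "run_workflow",
    "presentation_rng",
]


@dataclass(frozen=True)
class MeasureSpontaneousActivity:
    duration: float
    #: direct-stimulation protocols (e.g. current injection): accepted and
    #: logged; no built-in protocols execute them in this release
    direct_stimulation: tuple = ()


@dataclass(frozen=True)
class MeasureOrientationTuningFullfield:
    num_orientations: int
    spatial_frequency: float = 0.8
    temporal_frequency: float = 2.0
    grating_duration: float = 147 * 7.0
    contrasts: tuple[float, ...] = (100.0,)
    num_trials: int = 1
    direct_stimulation: tuple = ()

    def __post_init__(self) -> None:
        if self.num_orientations < 1 or self.num_trials < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class MeasureSizeTuning:
    sizes: tuple[float, ...]
    orientation: float = 0.0
    spatial_frequency: float = 0.8
    temporal_frequency: float = 2.0
    contrast: float = 100.0
    duration: float = 147 * 7.0
    num_trials: int = 1
    direct_stimulation: tuple = ()


ExperimentSpec = (MeasureSpontaneousActivity | MeasureOrientationTuningFullfield
                  | MeasureSizeTuning)


@dataclass
class WorkflowConfig:
    model_name: str
    results_dir: str | Path
    reset: bool = False
    null_stimulus_period: float = 140.0
    seed: int = 0


def enumerate_stimuli(exp: ExperimentSpec) -> list[StimulusDescriptor]:
    """The deterministic stimulus list of one experiment.

    Orientation tuning enumerates ``theta_i = i*pi/num_orientations`` in the
    order (orientation, contrast, trial); size tuning (size, trial).
    """
    if isinstance(exp, MeasureSpontaneousActivity):
        return [StimulusDescriptor(NULL, duration=exp.duration)]
    if isinstance(exp, MeasureOrientationTuningFullfield):
        out = []
        for i in range(exp.num_orientations):
            theta = i * math.pi / exp.num_orientations
            for contrast in exp.contrasts:
                for trial in range(exp.num_trials):
                    out.append(StimulusDescriptor(
                        FULLFIELD_GRATING,
                        duration=exp.grating_duration,
                        trial=trial,
                        orientation=theta,
                        spatial_frequency=exp.spatial_frequency,
                        temporal_frequency=exp.temporal_frequency,
                        contrast=float(contrast),
                    ))
        return out
    if isinstance(exp, MeasureSizeTuning):
        out = []
        for size in exp.sizes:
            for trial in range(exp.num_trials):
                out.append(StimulusDescriptor(
                    GRATING_DISK,
                    duration=exp.duration,
                    trial=trial,
                    orientation=exp.orientation,
                    spatial_frequency=exp.spatial_frequency,
                    temporal_frequency=exp.temporal_frequency,
                    contrast=exp.contrast,
                    size=float(size),
                ))
        return out
    raise TypeError(f"unknown experiment spec {type(exp).__name__}")


def dedup_stimuli(stimuli: Sequence[StimulusDescriptor],
                  store: DataStore | DataStoreView) -> list[StimulusDescriptor]:
    """Drop stimuli whose identity string already annotates a stored
    segment; order preserved."""
    view = store.full_view() if isinstance(store, DataStore) else store
    seen = {identity_to_string(seg.stimulus)
            for seg in view.segments if seg.stimulus is not None}
    return [s for s in stimuli if identity_to_string(s.identity()) not in seen]


def presentation_rng(master_seed: int, identity_string: str) -> np.random.Generator:
    """Per-presentation random stream derived from (seed, identity) so
    deduplication does not shift the randomness of later stimuli."""
    digest = hashlib.sha256(f"{master_seed}:{identity_string}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2 ** 31))


def run_workflow(config: WorkflowConfig,
                 model_builder: Callable[[np.random.Generator], Model],
                 experiments: Sequence[ExperimentSpec]) -> DataStore:
    """Build the model, run every experiment, store and save everything."""
    results_dir = Path(config.results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    log_path = results_dir / "workflow.log"
    log_fh = open(log_path, "a", encoding="utf-8")

    def log(msg: str) -> None:
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        print(line)
        log_fh.write(line + "\n")
        log_fh.flush()

    try:
        master_rng = np.random.default_rng(config.seed)
        try:
            model = model_builder(master_rng)
        except Exception as exc:
            raise RuntimeError(f"model build failed: {exc}") from exc
        store_dir = results_dir / "datastore"
        if (store_dir / "index.json").exists():
            store = load(store_dir)
            log(f"loaded existing datastore with {len(store.segments)} segment(s)")
        else:
            store = DataStore(config.model_name)
        engine = model.engine(master_rng)

        n_done = 0
        for exp_index, exp in enumerate(experiments):
            stimuli = enumerate_stimuli(exp)
            todo = dedup_stimuli(stimuli, store)
            log(f"experiment {exp_index + 1}/{len(experiments)} "
                f"({type(exp).__name__}): {len(todo)}/{len(stimuli)} stimuli to run")
            if getattr(exp, "direct_stimulation", ()):
                log(f"  note: {len(exp.direct_stimulation)} direct-stimulation "
                    "entries accepted but not executed (no built-in protocols)")
            for stim in todo:
                id_string = identity_to_string(stim.identity())
                rng = presentation_rng(config.seed, id_string)
                segments = present_stimulus(model, stim, engine, rng)
                for seg in segments:
                    store.add_segment(seg)
                n_done += 1
                log(f"presented stimulus {n_done}: {id_string}")
                store.experiment_log.append(id_string)
                blank = (None if config.reset
                         else blank_input_spikes(model, config.null_stimulus_period, rng))
                inter_presentation(engine, config.reset,
                                   config.null_stimulus_period, rng, blank)
        try:
            save(store, store_dir)
        except OSError as exc:
            raise RuntimeError(f"failed to save datastore to {store_dir}: {exc}") from exc
        log(f"workflow complete: {len(store.segments)} segment(s) in store")
        return store
    finally:
        log_fh.close()
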