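# circuitbench

An integrated workflow system for *virtual experiments* on spiking neuronal
networks, aimed at modellers who want to go from a declarative model
description to analysed, plotted results with a single command — without
hand-writing the glue between stimulus generation, simulation, storage,
analysis and figures.

The package covers the full experimental cycle at desk scale:

- **Declarative configuration** — hierarchical parameter trees in a
  restricted Python-literal dialect with file inclusion (`url("...")`),
  cross-references with arithmetic (`ref('a.b.c')*2`), distribution
  literals (`UniformDist(min=, max=)`), required-parameter validation and
  dotted-path overrides.
- **Model construction** — 2D neuron *sheets* with cortical coordinates and
  magnification-factor retinotopy; *modular connectors* that combine named
  kernel functions through an arithmetic expression into a per-target
  sampling distribution; a difference-of-Gaussians retina/LGN front-end
  emitting ON/OFF Poisson spike trains; synthetic orientation maps.
- **Simulation** — a self-contained clock-driven simulator for
  conductance-based and current-based exponential-synapse
  integrate-and-fire neurons with delayed delivery, Tsodyks–Markram
  short-term plasticity and per-neuron background Poisson noise.
- **Storage & queries** — every recording is annotated with the full
  stimulus identity; `param_filter_query` filters recordings and analysis
  products by any declared parameter; stores round-trip to disk bit-exactly.
- **Analysis & figures** — trial-averaged firing rates, CV of
  inter-spike intervals, population summaries, tuning curves; hierarchical
  figure trees (rasters, conductance/Vm overviews, parameter-grid panels).
- **Meta-workflow** — grid parameter searches with per-run directories, a
  manifest, cross-run collation of `SingleValue` products, and the
  Vogels–Abbott sparse-network benchmark builder.

## The models at the core

**Neurons.** Leaky integrate-and-fire with exponential synapses
(`IF_cond_exp` / `IF_curr_exp`). For the conductance-based neuron,

```
cm dv/dt = -(cm/tau_m)(v - v_rest) + g_e(t)(e_rev_E - v) + g_i(t)(e_rev_I - v) + i_offset
```

with `g_e, g_i` decaying as `exp(-t/tau_syn)` between presynaptic events.
Integration is exponential-Euler at `dt = 0.1 ms`; a threshold crossing at
`v_thresh` emits a spike, resets to `v_reset` and clamps for `tau_refrac`.

**Synapses.** Optional Tsodyks–Markram short-term plasticity: a spike
releases a fraction `u·x` of the synaptic resource (scaling the delivered
weight), depletes `x`, and increments `u` by `U(1-u)`; `x` recovers with
`tau_rec`, `u` decays to `U` with `tau_fac`.

**Connectivity.** Per source–target pair, named kernel functions —
distance (`exp(-alpha*sqrt(theta^2 + d^2))`), push–pull
(Gaussian in circular orientation and phase offsets; inhibitory
projections peak at *opposite* phase), Gabor afferent fields — are
combined by a configured expression such as `'f1*f2'`, clipped at zero,
normalized, and `num_samples` synapses are drawn per target.

**Stimuli.** Drifting sinusoidal gratings in a sampled visual space:
`L(x,y,t) = bg·(1 + (C/100)·sin(2π·SF·(x cosθ + y sinθ) − 2π·TF·t/1000))`,
optionally confined to a disk aperture, plus blank (background) stimuli.

## Worked example

The packaged example configuration (`circuitbench.examples`) describes a
push–pull model of layer 4 of primary visual cortex: ON/OFF LGN mosaics
project through Gabor-shaped receptive fields (orientation and phase
assigned from an orientation map) to excitatory and inhibitory sheets with
push–pull lateral connectivity. `desk_scale_tree` shrinks it to ~200
cortical neurons for a quick run:

```python
import numpy as np
from circuitbench.examples import load_example_tree, desk_scale_tree
from circuitbench.model import build_push_pull_model
from circuitbench.experiments import (MeasureSpontaneousActivity,
    MeasureOrientationTuningFullfield, WorkflowConfig, run_workflow)
from circuitbench.datastore import param_filter_query
from circuitbench.analysis import trial_averaged_firing_rate, population_summary

tree = desk_scale_tree(load_example_tree("work"))
config = WorkflowConfig(model_name="push-pull demo", results_dir="results", seed=1)
experiments = [
    MeasureSpontaneousActivity(duration=42 * 7.0),
    MeasureOrientationTuningFullfield(num_orientations=2,
        grating_duration=42 * 7.0, contrasts=(100.0,), num_trials=2),
]
store = run_workflow(config,
    lambda rng: build_push_pull_model(tree, rng, base_dir="work"), experiments)

dsv = param_filter_query(store, st_name="FullfieldDriftingSinusoidalGrating",
                         sheet_name="V1_Exc_L4")
trial_averaged_firing_rate(dsv)
print(population_summary(dsv, "mean_rate", sheet_name="V1_Exc_L4").value)
```

The run logs one line per presented stimulus and ends with

```
[09:21:37] workflow complete: 20 segment(s) in store
```

— 5 stimuli (one blank + 2 orientations × 2 trials) × 4 recorded sheets.
The analysis then adds one `PerNeuronValue` firing-rate product per
orientation (here mean rates 105.0 and 105.8 spikes/s across the
excitatory sheet — strongly noise-driven at this small scale) and the
population summaries print

```
Mean(firing rate) = 105.4 spikes/s
Mean(CV of ISI squared) = 0.99
```

A CV² near 1 says the spiking is Poisson-like irregular. Re-running the
same command is a no-op: stimuli already in the store are deduplicated.

The same workflow is available from the shell:

```
circuitbench validate work/top.param
circuitbench run work/top.param --experiments exps.json --results-dir results --seed 1
circuitbench query results/datastore sheet_name=V1_Exc_L4 --count
circuitbench search work/top.param --param a.b=0.1,0.2 --master search --experiments exps.json
circuitbench collate search --filter sheet_name=V1_Exc_L4 --out grid.png
```

## Datastore directory format (version 1)

A saved store is a directory holding `index.json` — segment and analysis
metadata, with stimulus identities as canonical strings — plus one `.npz`
array container per segment (spike trains and analog signals). The format
is versioned; loading rejects unknown versions. Within a format version
the layout is stable.

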