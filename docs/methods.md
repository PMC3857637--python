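# Methods

This note records the models implemented in circuitbench, the choices made
where the design was genuinely open, and what the package's synthetic
benchmarks do and do not demonstrate.

## Configuration dialect

Configuration files are parsed with Python's `ast` module as a restricted
literal grammar: mappings with string keys, numeric/string/boolean/tuple
scalars, `url("relative/path")` inclusion (resolved relative to the
including file, with cycle detection), `ref('dotted.path')` references,
`UniformDist(min=, max=)` / `PyNNDistribution(name='uniform', params=(a,b))`
distribution literals, and arithmetic (`+ - * /`, unary minus,
parentheses) over references and numbers. Reference resolution is a
fixed-point iteration bounded by node count: each pass replaces every
reference whose target is itself fully resolved, so chains and forward
references work; a stalled pass distinguishes dangling paths from cycles.
Validation reports missing keys, type mismatches and *unknown* keys — the
last as typo protection, a deliberate choice since silent extra keys are a
common configuration failure mode. Only relative `url()` paths are
accepted.

## Stimuli

The visual space is sampled at pixel centres on a half-open grid (default
10 px/deg). The drifting grating luminance is

    L(x,y,t) = bg · (1 + (C/100) · sin(2π·SF·(x cosθ + y sinθ) − 2π·TF·t/1000)),

contrast defined as a Michelson percentage about the background, θ the
direction of the spatial-frequency vector measured counter-clockwise from
the +x axis (stripes perpendicular to it), initial spatial phase zero, and
drift along +θ. The disk variant resets pixels beyond `size/2` degrees
from the field centre to background. Frame count is
`ceil(duration/update_interval)`.

## Retina / LGN front-end

The retino-thalamic pathway is abstracted as mirrored ON/OFF relay
mosaics (shared positions, so the ON drive is the exact negative of the
OFF drive). Each cell applies a spatial difference-of-Gaussians to the
contrast image `(L-bg)/bg` — each lobe discretely normalized to unit sum
and scaled by `A_c` / `A_s`, so the balanced default (`A_c = A_s = 1`)
cancels exactly on uniform frames — followed by a first-order exponential
low-pass (`tau_lgn = 10 ms`) across frames with zero initial state. Rates
are `clip(r0 + gain·s·drive, 0, r_max)` with `s = ±1` for ON/OFF, and
spikes are an inhomogeneous Poisson process with the rate held constant
over each frame interval. Defaults: `σ_c = 0.2°`, `σ_s = 0.6°`,
`r0 = 10 /s`, `gain = 100 /s` per unit drive, `r_max = 200 /s`, mosaic
density 20 cells/deg² per polarity. These values give contrast responses
in the physiological range at desk scale; all are configurable. This
front-end deliberately omits contrast gain control, space–time-inseparable
kernels and retinal nonlinearity cascades.

## Sheets and retinotopy

Sheets place `round(density · area_mm²)` neurons uniformly at random on a
cortical rectangle; `density` is interpreted as neurons per mm², which
makes the example numbers (5×5 mm at 64/mm²) give a 1600-neuron sheet.
Retinotopy is linear: visual position = cortical position divided by the
magnification factor (µm/deg), sheet centre anchored at the visual-field
centre. Orientation preference is a bilinear sample of an orientation map
taken in the doubled-angle complex representation (so interpolation
respects the π period); phase preference is drawn from the configured
distribution.

The synthetic orientation-map generator superimposes `K` plane waves with
wave vectors drawn uniformly from an annulus around magnitude
`2π/period` (relative width 0.5) with random directions and phases, and
takes half the argument of the complex sum. The construction is isotropic,
so orientations are uniform on [0, π); the magnitude spread makes spatial
correlations decay within a few periods (a single-ring spectrum would
give Bessel-type long-range correlations). Real orientation maps have
pinwheel statistics and anisotropies this construction does not emulate;
it provides smoothness, periodicity and uniform coverage, which is what
the connectivity rules consume.

## Modular connectors

Per target neuron, every named kernel function is evaluated over all
source neurons, the weight expression combines them elementwise, negative
values are clipped to zero (probabilities must be non-negative), the
result is normalized, and `num_samples` sources are drawn i.i.d. *with
replacement*; multapses are kept as separate synapses. Sampling with
replacement makes "incoming synapse count = num_samples" an exact
invariant, which the tests rely on. An all-zero distribution for some
target is an error naming that target. Delays come from the delay
expression (clamped at one simulator step); weights are the projection's
`base_weight`.

Kernel forms:

- distance: `exp(-α·sqrt(θ² + d²))` with `d` the cortical distance in µm —
  a smooth hyperbolic fall-off consistent with the magnitudes of the
  example parameters (θ = 207.76 µm, α = 0.013944 /µm); the kernel is
  pluggable should a different fall-off be wanted;
- push–pull: Gaussians in the circular orientation difference (period π)
  and phase difference (period 2π), the phase Gaussian centred at 0 for
  excitatory projections and at π for inhibitory ones — keyed on the
  projection's synapse type, which matches the description of inhibitory
  sources preferring anti-phase targets;
- Gabor afferent: `exp(-(a² + (ar·b)²)/(2·size²))·cos(2πf·a + phase)` in
  the target's RF frame (`a` across stripes, `b` along), ON cells sampling
  `max(G,0)` and OFF cells `max(-G,0)` — disjoint supports by
  construction. The configured afferent `num_samples` is split evenly
  between the ON and OFF projections.

The example's `weight_factor` is treated as the afferent projection's
`base_weight` (the configured reference arithmetic then gives twice the
lateral weight).

## Simulator

Fixed-step clock-driven integration, `dt = 0.1 ms`, recording period
1 ms (both configurable). Conductances decay exactly by `exp(-dt/τ)` per
step; the membrane uses the exponential-Euler update with conductances
frozen over the step, which is unconditionally stable for the leak.
Spikes are detected at end-of-step, stamped with the step's end time, and
delivered through a ring buffer after their synaptic delay. Time is
monotone across presentations (a global step counter), so short-term
plasticity state and in-flight deliveries remain consistent over a whole
experiment. Background noise adds two independent Poisson event streams
per neuron (excitatory and inhibitory weights in µS) drawn per step.

The short-term-plasticity parameters `u, tau_rec, tau_psc, tau_fac` are
interpreted in the standard resource/utilization model with `u` as the
utilization parameter `U`; `tau_psc` replaces the sheet's synaptic decay
constant for the plastic projection. In the depressing limit
(`tau_fac → 0`, `tau_rec → ∞`) the per-spike efficacies follow
`U, U(1-U), U(1-U)², …`, which the tests check against the closed-form
recursion.

Between presentations the controller either re-initializes all state
variables from their declared initial distributions (`reset = true`) or
runs a blank of `null_stimulus_period` ms with recording off, letting
activity relax to background so responses are independent of presentation
order.

## Workflow, storage, determinism

Each presentation's random stream is derived by hashing (master seed,
stimulus identity string), so deduplication of already-recorded stimuli
cannot shift the randomness of later ones, and identical seeds reproduce
identical segments exactly. Stimuli are presented in enumeration order —
presentations are independent by design, so order is immaterial. The
store keeps canonical identity strings (`Kind(name=value,...)`, sorted
names, shortest-round-trip float repr, equality by string equality); float
criteria compare with absolute tolerance 1e-9, periodic parameters modulo
their period. Saved stores are a JSON index plus one npz container per
segment; arrays round-trip bit-exactly.

## Analyses

Trial-averaged firing rate: per sheet and per stimulus identity stripped
of `trial`, `rate = total spikes / (n_trials · duration)`. CV of ISI uses
the population (n) denominator; trains with fewer than two intervals are
excluded from aggregates rather than contributing zeros. Population
summaries emit `SingleValue` products named exactly `Mean(firing rate)`
and `Mean(CV of ISI squared)`, which is what the cross-run collation of a
parameter search matches on. Tuning curves collate `PerNeuronValue`
products over a single stimulus kind, one curve per neuron per
combination of the residual parameters, x ascending; curves are not
centred on preferred values.

## Parameter search and benchmark

`combination_search` enumerates the cartesian product of value lists in
lexicographic path order, runs each combination in a directory named by
the sorted `path=value` pairs (parse-back tested), records failures in
the manifest and continues. Execution backends are a local sequential one
and a cluster-submission stub that records what it would submit. Grid
figures support one or two varied parameters, axis labels carrying the
full configuration paths; with three or more the call errors and advises
slicing the table.

The Vogels–Abbott benchmark builder makes an 80/20
excitatory/inhibitory split (standard for this model family) with
independent Bernoulli connectivity `p = k/N`, no self-connections,
conductance-based neurons by default (the current-based variant is a
parameter change). The realized mean in-degree is `(N-1)·p ≈ k`.

## Problem sizes and limitations

The shipped example is exercised at two scales: the full-scale
configuration (1600 + 400 cortical neurons, 6.8° field) for construction-
level checks (sheet building, recorder selection, connector sampling), and
a desk-scale variant (~200 cortical neurons, 3° field, 294 ms
presentations) for end-to-end workflow runs — sizes chosen so the entire
cycle, including figures, completes in seconds while leaving every
bookkeeping contract (segment counts, products per sheet, figure columns)
non-trivial. At this scale network activity is dominated by the
configured background noise rather than by recurrent structure, so the
end-to-end tests demonstrate workflow correctness, not cortical dynamics;
orientation-tuned responses emerge only at larger scales and longer
presentations. The simulator is single-process and makes no attempt at
distributed execution; plasticity of weights (long-term) and event-driven
exact integration are out of scope.
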