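"""Clock-driven simulation of exponential-synapse integrate-and-fire networks.

Neuron models are the conductance-based (``IF_cond_exp``) and current-based
(``IF_curr_exp``) leaky integrate-and-fire neurons with exponentially
decaying synapses.  Integration uses a fixed step ``dt`` (default 0.1 ms)
with the exponential-Euler update: synaptic conductances decay exactly by
``exp(-dt/tau_syn)`` each step, and the membrane relaxes toward the
effective equilibrium with conductances frozen over the step, which is
unconditionally stable for the leak term.  For ``IF_cond_exp``

    g_tot  = cm/tau_m + g_e + g_i
    v_inf  = (cm/tau_m * v_rest + g_e*e_rev_E + g_i*e_rev_I + i_offset) / g_tot
    v(t+dt) = v_inf + (v - v_inf) * exp(-dt * g_tot / cm)

(units: mV, ms, nF, uS, nA).  A threshold crossing detected at the end of a
step emits a spike stamped with the step's end time, resets ``v`` to
``v_reset`` and clamps it for ``tau_refrac``.  Spikes are delivered to
their targets after the synaptic delay through a ring buffer.

Short-term plasticity follows the standard Tsodyks-Markram resource /
utilization model: each presynaptic spike releases a fraction ``u*x`` of
the resource (the synaptic efficacy factor), depletes ``x`` accordingly,
and increments ``u`` toward 1 by ``U*(1-u)`` when facilitation is enabled;
between spikes ``x`` recovers to 1 with ``tau_rec`` and ``u`` decays to
``U`` with ``tau_fac``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .connectors import ConnectionList, TMParams
from .identities import Identity
from .sheets import Sheet

__all__ = [
    "NeuronModelParams",
    "RecordedSegment",
    "Network",
    "tm_efficacy",
    "run_presentation",
    "inter_presentation",
]

DEFAULT_DT = 0.1            # ms
DEFAULT_RECORD_PERIOD = 1.0  # ms


@dataclass(frozen=True)
class NeuronModelParams:
    model: str = "IF_cond_exp"
    v_rest: float = -70.0     # mV
    v_reset: float = -70.0    # mV
    v_thresh: float = -57.0   # mV
    tau_m: float = 10.0       # ms
    cm: float = 0.29          # nF
    tau_refrac: float = 2.0   # ms
    tau_syn_E: float = 1.5    # ms
    tau_syn_I: float = 10.0   # ms
    e_rev_E: float = 0.0      # mV (cond only)
    e_rev_I: float = -75.0    # mV (cond only)
    i_offset: float = 0.0     # nA

    def __post_init__(self) -> None:
        if self.model not in ("IF_cond_exp", "IF_curr_exp"):
            raise ValueError(f"unknown neuron model {self.model!r}")
        if min(self.tau_m, self.tau_syn_E, self.tau_syn_I) <= 0:
            raise ValueError("time constants must be > 0")
        if not self.v_thresh > self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")

    @classmethod
    def from_config(cls, model: str, params: Mapping[str, float]) -> "NeuronModelParams":
        known = {f for f in cls.__dataclass_fields__ if f != "model"}
        return cls(model=model, **{k: float(v) for k, v in params.items() if k in known})


@dataclass
class RecordedSegment:
    """Recordings from one sheet during one stimulus presentation."""

    sheet_name: str
    stimulus: Identity | None
    spike_ids: np.ndarray                       # neurons recorded for spikes
    spike_trains: dict[int, np.ndarray]         # neuron id -> spike times (ms)
    analog_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    analog: dict[str, np.ndarray] = field(default_factory=dict)  # var -> (n_samples, n_ids)
    t_start: float = 0.0
    t_stop: float = 0.0
    record_period: float = DEFAULT_RECORD_PERIOD
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.annotations.setdefault("spike_times_units", "ms")
        self.annotations.setdefault("v_units", "mV")
        self.annotations.setdefault("gsyn_units", "uS")

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def spike_train(self, neuron: int) -> np.ndarray:
        return self.spike_trains.get(int(neuron), np.empty(0))


# ---------------------------------------------------------------------------
# Tsodyks-Markram efficacies
# ---------------------------------------------------------------------------

def tm_efficacy(spike_times: Sequence[float], p: TMParams) -> np.ndarray:
    """Per-spike efficacy factors for a presynaptic spike train."""
    times = np.asarray(spike_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be increasing")
    x, u = 1.0, p.U
    out = np.empty(times.size)
    last = None
    for i, t in enumerate(times):
        if last is not None:
            delta = t - last
            x = 1.0 - (1.0 - x) * math.exp(-delta / p.tau_rec)
            u = p.U + (u - p.U) * math.exp(-delta / p.tau_fac) if p.tau_fac > 0 else p.U
        out[i] = u * x
        x -= u * x
        if p.tau_fac > 0:
            u += p.U * (1.0 - u)
        last = t
    return out


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

class _Projection:
    """Precomputed delivery structure for one ConnectionList."""

    def __init__(self, conn: ConnectionList, n_source: int, dt: float):
        self.conn = conn
        order = np.argsort(conn.source, kind="stable")
        self.targets = conn.target[order].astype(int)
        self.weights = conn.weight[order].astype(float)
        self.delay_steps = np.maximum(np.rint(conn.delay[order] / dt).astype(int), 1)
        counts = np.bincount(conn.source.astype(int), minlength=n_source)
        self.indptr = np.concatenate(([0], np.cumsum(counts)))
        self.stp = conn.short_term_plasticity
        if self.stp is not None:
            self.x = np.ones(n_source)
            self.u = np.full(n_source, self.stp.U)
            self.last = np.full(n_source, -np.inf)

    def reset_stp(self) -> None:
        if self.stp is not None:
            self.x.fill(1.0)
            self.u.fill(self.stp.U)
            self.last.fill(-np.inf)

    def deliver(self, spiking: np.ndarray, t: float, buffer: np.ndarray,
                channel: int, step: int, ring: int) -> None:
        for s in spiking:
            lo, hi = self.indptr[s], self.indptr[s + 1]
            if lo == hi:
                continue
            w = self.weights[lo:hi]
            if self.stp is not None:
                p = self.stp
                if np.isfinite(self.last[s]):
                    delta = t - self.last[s]
                    self.x[s] = 1.0 - (1.0 - self.x[s]) * math.exp(-delta / p.tau_rec)
                    self.u[s] = (p.U + (self.u[s] - p.U) * math.exp(-delta / p.tau_fac)
                                 if p.tau_fac > 0 else p.U)
                eff = self.u[s] * self.x[s]
                self.x[s] -= eff
                if p.tau_fac > 0:
                    self.u[s] += p.U * (1.0 - self.u[s])
                self.last[s] = t
                w = w * eff
            slots = (step + self.delay_steps[lo:hi]) % ring
            np.add.at(buffer, (slots, channel, self.targets[lo:hi]), w)


class _Population:
    """State of one integrate-and-fire sheet."""

    # channels: 0 = excitatory, 1 = inhibitory; STP synapses with tau_psc
    # different from the sheet default get extra channels.
    def __init__(self, sheet: Sheet, params: NeuronModelParams, dt: float,
                 rng: np.random.Generator):
        self.sheet = sheet
        self.p = params
        self.n = sheet.size
        self.dt = dt
        self.channel_tau = [params.tau_syn_E, params.tau_syn_I]
        self.channel_kind = ["exc", "inh"]
        self.g = np.zeros((2, self.n))
        self.v = np.empty(self.n)
        self.refrac = np.zeros(self.n, dtype=int)
        self.refrac_steps = max(int(round(params.tau_refrac / dt)), 0)
        self.initialize(rng)

    def channel_for(self, kind: str, tau: float | None) -> int:
        base = 0 if kind == "exc" else 1
        if tau is None or abs(tau - self.channel_tau[base]) < 1e-12:
            return base
        for i, (k, t) in enumerate(zip(self.channel_kind, self.channel_tau)):
            if k == kind and abs(t - tau) < 1e-12:
                return i
        self.channel_kind.append(kind)
        self.channel_tau.append(tau)
        self.g = np.vstack([self.g, np.zeros((1, self.n))])
        return len(self.channel_tau) - 1

    def initialize(self, rng: np.random.Generator) -> None:
        init_v = self.sheet.initial_state.get("v")
        if init_v is not None and len(init_v) == self.n:
            # re-sample per reset so resets are genuinely re-initializations
            from .config import DistributionSpec, sample_distribution
            dist = self.sheet.spec.initial_values.get("v")
            if isinstance(dist, DistributionSpec):
                self.v[:] = sample_distribution(dist, rng, size=self.n)
            else:
                self.v[:] = init_v
        else:
            self.v.fill(self.p.v_rest)
        self.g.fill(0.0)
        self.refrac.fill(0)

    def finalize_decays(self) -> None:
        self.decay = np.exp(-self.dt / np.asarray(self.channel_tau))[:, np.newaxis]
        self.exc_mask = np.array([k == "exc" for k in self.channel_kind])

    def step(self, extra_current: np.ndarray | None = None) -> np.ndarray:
        """Advance one step; returns indices of neurons that spiked."""
        p = self.p
        g_e = self.g[self.exc_mask].sum(axis=0)
        g_i = self.g[~self.exc_mask].sum(axis=0)
        i_ext = p.i_offset if extra_current is None else p.i_offset + extra_current
        if p.model == "IF_cond_exp":
            g_leak = p.cm / p.tau_m
            g_tot = g_leak + g_e + g_i
            v_inf = (g_leak * p.v_rest + g_e * p.e_rev_E + g_i * p.e_rev_I + i_ext) / g_tot
            v_new = v_inf + (self.v - v_inf) * np.exp(-self.dt * g_tot / p.cm)
        else:  # IF_curr_exp: channels carry currents (nA), g_i weights < 0 by sign
            i_syn = g_e - g_i
            v_inf = p.v_rest + (i_syn + i_ext) * p.tau_m / p.cm
            v_new = v_inf + (self.v - v_inf) * math.exp(-self.dt / p.tau_m)
        in_refrac = self.refrac > 0
        v_new[in_refrac] = p.v_reset
        self.refrac[in_refrac] -= 1
        spiking = np.flatnonzero(v_new >= p.v_thresh)
        if spiking.size:
            v_new[spiking] = p.v_reset
            self.refrac[spiking] = self.refrac_steps
        self.v = v_new
        self.g *= self.decay
        return spiking


class Network:
    """Sheets + projections + background noise, ready to simulate.

    Spike-source sheets (cell model ``SpikeSource``) carry no state; their
    spike trains are supplied per presentation (the LGN mosaics).
    """

    def __init__(self, dt: float = DEFAULT_DT,
                 record_period: float = DEFAULT_RECORD_PERIOD):
        self.dt = dt
        self.record_period = record_period
        self.sheets: dict[str, Sheet] = {}
        self.models: dict[str, NeuronModelParams | None] = {}
        self.connections: list[ConnectionList] = []
        self.recorded: dict[str, dict[str, tuple[np.ndarray, tuple[str, ...]]]] = {}

    def add_sheet(self, sheet: Sheet, model: NeuronModelParams | None = None) -> None:
        if sheet.name in self.sheets:
            raise ValueError(f"duplicate sheet {sheet.name!r}")
        if model is None and sheet.spec.cell_model != "SpikeSource":
            model = NeuronModelParams.from_config(
                sheet.spec.cell_model, sheet.spec.cell_params
            )
        self.sheets[sheet.name] = sheet
        self.models[sheet.name] = model

    def add_projection(self, conn: ConnectionList) -> None:
        for name in (conn.source_sheet, conn.target_sheet):
            if name not in self.sheets:
                raise ValueError(f"projection references unknown sheet {name!r}")
        self.connections.append(conn)

    def is_source(self, name: str) -> bool:
        return self.models[name] is None

    def select_recorders(self, rng: np.random.Generator) -> None:
        """Materialize every sheet's recorder specs into neuron id sets.

        Done once per network so the same neurons are recorded for every
        stimulus presentation.
        """
        from .sheets import select_random_n

        self.recorded = {}
        for name, sheet in self.sheets.items():
            per_sheet = {}
            for label, rec in sheet.spec.recorders.items():
                ids = select_random_n(sheet, rec.num_of_cells, rng)
                per_sheet[label] = (np.sort(ids), tuple(rec.variables))
            if per_sheet:
                self.recorded[name] = per_sheet


# ---------------------------------------------------------------------------
# Simulation engine
# ---------------------------------------------------------------------------

class SimulationEngine:
    """Holds integration state across presentations of one network."""

    def __init__(self, network: Network, rng: np.random.Generator):
        self.net = network
        self.dt = network.dt
        self.pops: dict[str, _Population] = {}
        for name, sheet in network.sheets.items():
            model = network.models[name]
            if model is not None:
                self.pops[name] = _Population(sheet, model, self.dt, rng)
        self.projections: list[tuple[str, str, int, _Projection]] = []
        max_delay = 1
        for conn in network.connections:
            n_src = network.sheets[conn.source_sheet].size
            proj = _Projection(conn, n_src, self.dt)
            pop = self.pops[conn.target_sheet]
            kind = "exc" if conn.target_synapses == "excitatory" else "inh"
            tau = conn.short_term_plasticity.tau_psc if conn.short_term_plasticity else None
            channel = pop.channel_for(kind, tau)
            self.projections.append((conn.source_sheet, conn.target_sheet, channel, proj))
            if proj.delay_steps.size:
                max_delay = max(max_delay, int(proj.delay_steps.max()))
        self.ring = max_delay + 1
        self.buffers: dict[str, np.ndarray] = {}
        for name, pop in self.pops.items():
            pop.finalize_decays()
            self.buffers[name] = np.zeros((self.ring, len(pop.channel_tau), pop.n))
        # global step counter: time is monotone across presentations so that
        # ring-buffer phase and STP inter-spike intervals stay consistent
        self.global_step = 0

    def reset_state(self, rng: np.random.Generator) -> None:
        for pop in self.pops.values():
            pop.initialize(rng)
        for _, _, _, proj in self.projections:
            proj.reset_stp()
        for buf in self.buffers.values():
            buf.fill(0.0)

    def run(self, input_spikes: Mapping[str, Sequence[np.ndarray]] | None,
            duration: float, rng: np.random.Generator,
            stimulus: Identity | None = None,
            record: bool = True) -> list[RecordedSegment]:
        net = self.net
        dt = self.dt
        n_steps = int(round(duration / dt))
        rec_steps = max(int(round(net.record_period / dt)), 1)
        n_samples = int(math.ceil(duration / net.record_period)) if duration > 0 else 0

        # Pre-bin source-sheet spikes by step (spike at t delivered from step floor(t/dt)).
        source_events: dict[str, list[np.ndarray]] = {}
        input_spikes = input_spikes or {}
        for name, trains in input_spikes.items():
            if not net.is_source(name):
                raise ValueError(f"{name!r} is not a spike-source sheet")
            per_step: list[list[int]] = [[] for _ in range(n_steps)]
            for cell, train in enumerate(trains):
                for t in train:
                    step = int(t / dt)
                    if 0 <= step < n_steps:
                        per_step[step].append(cell)
            source_events[name] = [np.asarray(cells, int) for cells in per_step]

        # Background noise: Poisson event counts per step, per neuron.
        bg = {}
        for name, pop in self.pops.items():
            noise = net.sheets[name].spec.background_noise
            bg[name] = noise

        # Recording setup.
        recording: dict[str, dict] = {}
        if record:
            for name, per_sheet in net.recorded.items():
                spike_ids: set[int] = set()
                analog_ids: set[int] = set()
                analog_vars: set[str] = set()
                for ids, variables in per_sheet.values():
                    if "spikes" in variables:
                        spike_ids.update(int(i) for i in ids)
                    avars = [v for v in variables if v != "spikes"]
                    if avars:
                        analog_ids.update(int(i) for i in ids)
                        analog_vars.update(avars)
                if not spike_ids and not analog_ids:
                    continue
                aids = np.array(sorted(analog_ids), dtype=int)
                recording[name] = {
                    "spike_ids": np.array(sorted(spike_ids), dtype=int),
                    "trains": {i: [] for i in sorted(spike_ids)},
                    "analog_ids": aids,
                    "analog": {v: np.zeros((n_samples, aids.size))
                               for v in sorted(analog_vars)},
                }

        step0 = self.global_step
        for step in range(n_steps):
            gstep = step0 + step
            t_end = (step + 1) * dt
            t_abs_end = (gstep + 1) * dt
            # analog snapshot at sample times k * record_period (start of step)
            if record and step % rec_steps == 0:
                k = step // rec_steps
                for name, recdata in recording.items():
                    pop = self.pops.get(name)
                    if pop is None or recdata["analog_ids"].size == 0:
                        continue
                    aids = recdata["analog_ids"]
                    for var, arr in recdata["analog"].items():
                        if k >= n_samples:
                            continue
                        if var == "v":
                            arr[k] = pop.v[aids]
                        elif var == "gsyn_exc":
                            arr[k] = pop.g[pop.exc_mask].sum(axis=0)[aids]
                        elif var == "gsyn_inh":
                            arr[k] = pop.g[~pop.exc_mask].sum(axis=0)[aids]

            # deliver source-sheet spikes scheduled for this step
            for name, events in source_events.items():
                spiking = events[step]
                if spiking.size == 0:
                    continue
                t_now = gstep * dt
                for src, tgt, channel, proj in self.projections:
                    if src == name:
                        proj.deliver(spiking, t_now, self.buffers[tgt],
                                     channel, gstep, self.ring)

            for name, pop in self.pops.items():
                buf = self.buffers[name]
                slot = gstep % self.ring
                pop.g += buf[slot]
                buf[slot] = 0.0
                noise = bg[name]
                if noise.exc_firing_rate > 0:
                    counts = rng.poisson(noise.exc_firing_rate * dt / 1000.0, pop.n)
                    pop.g[0] += counts * noise.exc_weight
                if noise.inh_firing_rate > 0:
                    counts = rng.poisson(noise.inh_firing_rate * dt / 1000.0, pop.n)
                    pop.g[1] += counts * noise.inh_weight
                spiking = pop.step()
                if spiking.size:
                    for src, tgt, channel, proj in self.projections:
                        if src == name:
                            proj.deliver(spiking, t_abs_end, self.buffers[tgt],
                                         channel, gstep, self.ring)
                    if record and name in recording:
                        trains = recording[name]["trains"]
                        for i in spiking:
                            if int(i) in trains:
                                trains[int(i)].append(t_end)

        self.global_step = step0 + n_steps
        segments: list[RecordedSegment] = []
        if record:
            for name, recdata in recording.items():
                trains = {}
                if net.is_source(name):
                    # source sheets: recorded spikes are the input trains
                    for i in recdata["spike_ids"]:
                        src_trains = input_spikes.get(name, [])
                        trains[int(i)] = (np.asarray(src_trains[int(i)])
                                          if int(i) < len(src_trains) else np.empty(0))
                else:
                    for i, ts in recdata["trains"].items():
                        trains[i] = np.asarray(ts)
                segments.append(RecordedSegment(
                    sheet_name=name,
                    stimulus=stimulus,
                    spike_ids=recdata["spike_ids"],
                    spike_trains=trains,
                    analog_ids=recdata["analog_ids"],
                    analog=recdata["analog"],
                    t_start=0.0,
                    t_stop=duration,
                    record_period=net.record_period,
                ))
        return segments


def run_presentation(network: Network,
                     input_spikes: Mapping[str, Sequence[np.ndarray]] | None,
                     duration: float, rng: np.random.Generator,
                     stimulus: Identity | None = None,
                     engine: SimulationEngine | None = None,
                     record: bool = True) -> list[RecordedSegment]:
    """Simulate one stimulus presentation; returns a segment per recorded
    sheet, annotated with the stimulus identity.  Deterministic per seed."""
    if engine is None:
        engine = SimulationEngine(network, rng)
    return engine.run(input_spikes, duration, rng, stimulus, record)


def inter_presentation(engine: SimulationEngine, reset: bool,
                       null_stimulus_period: float, rng: np.random.Generator,
                       blank_input: Mapping[str, Sequence[np.ndarray]] | None = None
                       ) -> None:
    """Between presentations: either re-initialize the state variables
    (``reset=True``) or run a blank of ``null_stimulus_period`` ms with
    recording off so activity relaxes to background."""
    if reset:
        engine.reset_state(rng)
    elif null_stimulus_period > 0:
        engine.run(blank_input, null_stimulus_period, rng, None, record=False)
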