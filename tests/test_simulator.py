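"""Integrate-and-fire integration, short-term plasticity, recording."""

import math

import numpy as np
import pytest

from circuitbench.connectors import ConnectionList, TMParams
from circuitbench.sheets import BackgroundNoiseSpec, RecorderSpec, Sheet, SheetSpec
from circuitbench.simulator import (
    Network,
    NeuronModelParams,
    SimulationEngine,
    inter_presentation,
    run_presentation,
    tm_efficacy,
)
from circuitbench.config import DistributionSpec


def single_neuron_network(params: NeuronModelParams, dt=0.1,
                          noise=BackgroundNoiseSpec(), v0=None,
                          record=("spikes", "v")) -> Network:
    spec = SheetSpec(name="S", sx=100.0, sy=100.0, density=100.0,  # 1 neuron
                     magnification_factor=1000.0, cell_model=params.model,
                     background_noise=noise,
                     recorders={"all": RecorderSpec(num_of_cells=1,
                                                    variables=tuple(record))})
    sheet = Sheet(spec, np.zeros((1, 2)))
    if v0 is not None:
        sheet.initial_state["v"] = np.array([v0])
    net = Network(dt=dt)
    net.add_sheet(sheet, params)
    net.select_recorders(np.random.default_rng(0))
    return net


class TestMembraneIntegration:
    def test_rest_is_fixed_point(self, rng):
        params = NeuronModelParams(i_offset=0.0)
        net = single_neuron_network(params, v0=params.v_rest)
        seg = run_presentation(net, None, 100.0, rng)[0]
        assert np.allclose(seg.analog["v"], params.v_rest)

    def test_leak_matches_closed_form(self, rng):
        # v(t) - v_rest = (v0 - v_rest) * exp(-t/tau_m), dt = 0.01 ms
        params = NeuronModelParams(v_rest=-70.0, v_thresh=-50.0, tau_m=10.0)
        net = single_neuron_network(params, dt=0.01, v0=-60.0)
        net.record_period = 1.0
        seg = run_presentation(net, None, 50.0, np.random.default_rng(0))[0]
        t = np.arange(seg.analog["v"].shape[0]) * seg.record_period
        expected = -70.0 + 10.0 * np.exp(-t / 10.0)
        rel = np.abs(seg.analog["v"][:, 0] - expected) / 10.0
        assert rel.max() < 1e-6

    def test_constant_current_isi_matches_closed_form(self, rng):
        # current-based LIF driven by suprathreshold i_offset
        params = NeuronModelParams(
            model="IF_curr_exp", v_rest=-70.0, v_reset=-70.0, v_thresh=-57.0,
            tau_m=10.0, cm=0.29, tau_refrac=2.0, i_offset=0.5)
        dt = 0.1
        net = single_neuron_network(params, dt=dt, v0=-70.0, record=("spikes",))
        seg = run_presentation(net, None, 2000.0, rng)[0]
        spikes = seg.spike_train(0)
        assert spikes.size > 5
        drive = params.i_offset * params.tau_m / params.cm
        expected = params.tau_m * math.log(
            (drive + params.v_rest - params.v_reset)
            / (drive + params.v_rest - params.v_thresh)) + params.tau_refrac
        isi = np.diff(spikes)
        assert np.all(np.abs(isi - expected) <= dt + 1e-9)

    def test_dt_halving_convergence(self):
        # trajectory change < 0.1 mV max-abs when dt goes 0.1 -> 0.05
        traces = {}
        for dt in (0.1, 0.05):
            params = NeuronModelParams(v_rest=-70.0, v_thresh=-50.0, tau_m=10.0,
                                       i_offset=0.2)
            net = single_neuron_network(params, dt=dt, v0=-65.0)
            seg = run_presentation(net, None, 1000.0, np.random.default_rng(0))[0]
            traces[dt] = seg.analog["v"][:, 0]
        diff = np.abs(traces[0.1] - traces[0.05]).max()
        assert diff < 0.1


class TestTMEfficacy:
    P = TMParams(U=0.5, tau_rec=1100.0, tau_fac=50.0, tau_psc=1.5)

    def test_first_spike_efficacy_is_U(self):
        assert tm_efficacy([0.0], self.P)[0] == pytest.approx(0.5)

    def test_depressing_limit_recursion(self):
        # tau_fac -> 0, tau_rec -> inf: U, U(1-U), U(1-U)^2, ...
        p = TMParams(U=0.5, tau_rec=1e12, tau_fac=0.0)
        eff = tm_efficacy(np.arange(6) * 10.0, p)
        expected = 0.5 * (1 - 0.5) ** np.arange(6)
        assert np.allclose(eff, expected, rtol=1e-6)

    def test_full_recovery_after_long_interval(self):
        eff = tm_efficacy([0.0, 1e9], self.P)
        assert eff[1] == pytest.approx(self.P.U)

    def test_decreasing_spike_times_rejected(self):
        with pytest.raises(ValueError):
            tm_efficacy([5.0, 1.0], self.P)


class TestDeliveryAndSTP:
    def two_sheet_network(self, stp, weight=0.01, delay=2.0, dt=0.1):
        pre_spec = SheetSpec(name="PRE", sx=100.0, sy=100.0, density=0.0,
                             magnification_factor=1000.0, cell_model="SpikeSource")
        pre = Sheet(pre_spec, np.zeros((1, 2)))
        params = NeuronModelParams(v_thresh=-50.0)
        post_spec = SheetSpec(
            name="POST", sx=100.0, sy=100.0, density=100.0,
            magnification_factor=1000.0,
            recorders={"all": RecorderSpec(num_of_cells=1,
                                           variables=("spikes", "v", "gsyn_exc"))})
        post = Sheet(post_spec, np.zeros((1, 2)))
        net = Network(dt=dt)
        net.add_sheet(pre)
        net.add_sheet(post, params)
        net.add_projection(ConnectionList(
            source=np.array([0]), target=np.array([0]),
            weight=np.array([weight]), delay=np.array([delay]),
            target_synapses="excitatory", short_term_plasticity=stp,
            source_sheet="PRE", target_sheet="POST"))
        net.select_recorders(np.random.default_rng(0))
        return net

    def test_delayed_delivery_raises_conductance(self, rng):
        net = self.two_sheet_network(stp=None)
        seg = run_presentation(net, {"PRE": [np.array([10.0])]}, 50.0, rng)[0]
        g = seg.analog["gsyn_exc"][:, 0]
        assert np.all(g[:12] == 0.0)       # nothing before spike + 2 ms delay
        assert g[13] > 0.0

    def test_stp_disabled_equals_unit_efficacy_path(self, rng):
        # a TM synapse with U = 1, instant recovery == the static synapse
        spikes = {"PRE": [np.array([5.0, 10.0, 15.0, 30.0])]}
        net_static = self.two_sheet_network(stp=None)
        seg_a = run_presentation(net_static, spikes, 60.0,
                                 np.random.default_rng(1))[0]
        unit = TMParams(U=1.0, tau_rec=1e-6, tau_fac=0.0, tau_psc=1.5)
        net_unit = self.two_sheet_network(stp=unit)
        seg_b = run_presentation(net_unit, spikes, 60.0,
                                 np.random.default_rng(1))[0]
        assert np.array_equal(seg_a.analog["v"], seg_b.analog["v"])
        assert np.array_equal(seg_a.analog["gsyn_exc"], seg_b.analog["gsyn_exc"])

    def test_depression_shrinks_successive_jumps(self, rng):
        stp = TMParams(U=0.5, tau_rec=1100.0, tau_fac=0.0, tau_psc=1.5)
        net = self.two_sheet_network(stp=stp, weight=0.01)
        spikes = {"PRE": [np.array([5.0, 10.0])]}
        seg = run_presentation(net, spikes, 30.0, rng)[0]
        g = seg.analog["gsyn_exc"][:, 0]
        jump1 = g[8] - g[7]
        jump2 = g[13] - g[12]
        assert 0 < jump2 < jump1


class TestPresentationContract:
    def test_zero_duration_empty_segments(self, rng):
        net = single_neuron_network(NeuronModelParams())
        segs = run_presentation(net, None, 0.0, rng)
        assert len(segs) == 1
        assert segs[0].duration == 0.0
        assert segs[0].spike_train(0).size == 0

    def test_analog_sample_count(self, rng):
        net = single_neuron_network(NeuronModelParams())
        seg = run_presentation(net, None, 147.0, rng)[0]
        assert seg.analog["v"].shape[0] == 147  # duration / record period

    def test_background_noise_depolarizes(self, rng):
        # the printed background block on an unconnected conductance sheet
        noise = BackgroundNoiseSpec(exc_firing_rate=2000.0, exc_weight=0.00145,
                                    inh_firing_rate=2000.0, inh_weight=0.00030)
        params = NeuronModelParams()
        net = single_neuron_network(params, noise=noise, v0=params.v_rest)
        seg = run_presentation(net, None, 1000.0, rng)[0]
        v = seg.analog["v"][:, 0]
        assert v.mean() > params.v_rest
        assert np.isfinite(seg.spike_train(0)).all()

    def test_identical_seeds_identical_segments(self):
        noise = BackgroundNoiseSpec(exc_firing_rate=500.0, exc_weight=0.002,
                                    inh_firing_rate=500.0, inh_weight=0.001)
        results = []
        for _ in range(2):
            net = single_neuron_network(NeuronModelParams(), noise=noise)
            seg = run_presentation(net, None, 500.0, np.random.default_rng(9))[0]
            results.append(seg)
        assert np.array_equal(results[0].spike_train(0), results[1].spike_train(0))
        assert np.array_equal(results[0].analog["v"], results[1].analog["v"])


class TestInterPresentation:
    def make_engine(self, rng):
        spec = SheetSpec(
            name="S", sx=100.0, sy=100.0, density=500.0,
            magnification_factor=1000.0,
            initial_values={"v": DistributionSpec("uniform", -60.0, -50.0)},
            background_noise=BackgroundNoiseSpec(exc_firing_rate=500.0,
                                                 exc_weight=0.002),
            recorders={"all": RecorderSpec(num_of_cells=5, variables=("spikes",))})
        sheet = Sheet(spec, np.zeros((5, 2)))
        sheet.initial_state["v"] = np.full(5, -55.0)
        net = Network()
        net.add_sheet(sheet, NeuronModelParams())
        net.select_recorders(rng)
        return SimulationEngine(net, rng)

    def test_reset_reinitializes_within_distribution(self, rng):
        engine = self.make_engine(rng)
        engine.run(None, 200.0, rng, record=False)
        inter_presentation(engine, reset=True, null_stimulus_period=140.0, rng=rng)
        v = engine.pops["S"].v
        assert np.all((v >= -60.0) & (v <= -50.0))

    def test_blank_emits_no_segment(self, rng):
        engine = self.make_engine(rng)
        before = len(engine.net.sheets)
        inter_presentation(engine, reset=False, null_stimulus_period=140.0, rng=rng)
        assert len(engine.net.sheets) == before  # nothing recorded, no side effects

    def test_reset_plus_same_seed_reproduces_spikes(self):
        # two consecutive identical presentations, each preceded by a reset
        # from the same seed, give identical spike trains
        rng = np.random.default_rng(2)
        engine = self.make_engine(rng)
        engine.run(None, 100.0, rng, record=False)  # warm-up
        inter_presentation(engine, True, 0.0, np.random.default_rng(55))
        seg1 = engine.run(None, 300.0, np.random.default_rng(77))
        inter_presentation(engine, True, 0.0, np.random.default_rng(55))
        seg2 = engine.run(None, 300.0, np.random.default_rng(77))
        for a, b in zip(seg1, seg2):
            for i in a.spike_ids:
                assert np.array_equal(a.spike_train(i), b.spike_train(i))
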