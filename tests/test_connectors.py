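"""Modular connectors: kernels, expressions, probabilistic sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from circuitbench.connectors import (
    ConnectorError,
    ConnectorFunctionSpec,
    ModularConnectorSpec,
    TMParams,
    eval_expression,
    gabor_value,
    hyperbolic_value,
    pushpull_value,
    sample_connections,
)
from circuitbench.sheets import Sheet, SheetSpec


def toy_sheet(name, positions, orientation=None, phase=None):
    spec = SheetSpec(name=name, sx=1000.0, sy=1000.0, density=0.0,
                     magnification_factor=1000.0)
    sheet = Sheet(spec, np.asarray(positions, dtype=float))
    if orientation is not None:
        sheet.metadata["orientation"] = np.asarray(orientation, dtype=float)
    if phase is not None:
        sheet.metadata["phase"] = np.asarray(phase, dtype=float)
    return sheet


class TestExpressions:
    def test_product_of_functions(self):
        out = eval_expression("f1*f2", {"f1": np.array([1.0, 2.0]),
                                        "f2": np.array([3.0, 4.0])})
        assert np.array_equal(out, [3.0, 8.0])

    def test_bare_numeral_constant(self):
        out = eval_expression("2", {}, length=5)
        assert np.array_equal(out, np.full(5, 2.0))

    def test_unknown_name_reported(self):
        with pytest.raises(ConnectorError, match="g1"):
            eval_expression("g1+f1", {"f1": np.array([1.0])})

    def test_division_by_zero_rejected(self):
        with pytest.raises(ConnectorError, match="division"):
            eval_expression("f1/0", {"f1": np.array([1.0])})


class TestHyperbolicKernel:
    def test_printed_parameters_at_origin(self):
        # theta = 207.76 um, alpha = 0.013944 /um -> exp(-2.8970)
        assert hyperbolic_value(0.0, 207.76, 0.013944) == pytest.approx(0.05524, abs=1e-4)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 2000, 50)
        v = hyperbolic_value(d, 207.76, 0.013944)
        assert np.all(np.diff(v) < 0)

    def test_zero_alpha_is_flat_one(self):
        assert np.allclose(hyperbolic_value(np.array([0.0, 500.0]), 207.76, 0.0), 1.0)


class TestPushPullKernel:
    def test_excitatory_peak_in_phase(self):
        assert pushpull_value(0.0, 0.0, 0.26, 0.52, "excitatory") == pytest.approx(1.0)

    def test_inhibitory_peak_anti_phase(self):
        assert pushpull_value(0.0, math.pi, 0.26, 0.52, "inhibitory") == pytest.approx(1.0)

    def test_one_sigma_orientation_offset(self):
        v = pushpull_value(0.26, 0.0, 0.26, 0.52, "excitatory")
        assert v == pytest.approx(math.exp(-0.5), abs=1e-4)

    def test_circular_orientation_distance(self):
        # pi-periodic: offset pi is zero offset
        assert pushpull_value(math.pi, 0.0, 0.26, 0.52, "excitatory") == pytest.approx(1.0)


class TestGaborKernel:
    def test_peak_at_origin_phase_zero(self):
        assert gabor_value(0.0, 0.0, 0.0, 0.0, 0.8, 0.46, 0.57) == pytest.approx(1.0)
        assert gabor_value(0.0, 0.0, 0.0, 0.0, 0.8, 0.46, 0.57, "ON") == pytest.approx(1.0)
        assert gabor_value(0.0, 0.0, 0.0, 0.0, 0.8, 0.46, 0.57, "OFF") == 0.0

    def test_antiphase_flips_polarity(self):
        assert gabor_value(0.0, 0.0, 0.0, math.pi, 0.8, 0.46, 0.57, "ON") == 0.0
        assert gabor_value(0.0, 0.0, 0.0, math.pi, 0.8, 0.46, 0.57, "OFF") == pytest.approx(1.0)

    def test_printed_afferent_parameters_off_axis(self):
        # across-stripe offset 0.5 deg with the configured RF parameters
        g = gabor_value(0.0, 0.5, 0.0, 0.0, 0.8, 0.46, 0.57)
        expected = math.exp(-0.25 / (2 * 0.46 ** 2)) * math.cos(0.8 * math.pi)
        assert expected == pytest.approx(-0.4481, abs=1e-3)
        assert g == pytest.approx(expected, abs=1e-12)

    def test_on_off_supports_disjoint(self, rng):
        dx = rng.uniform(-2, 2, 500)
        dy = rng.uniform(-2, 2, 500)
        on = gabor_value(dx, dy, 0.7, 1.1, 0.8, 0.46, 0.57, "ON")
        off = gabor_value(dx, dy, 0.7, 1.1, 0.8, 0.46, 0.57, "OFF")
        assert np.all(on * off == 0.0)


def lateral_spec(**kw):
    """The printed lateral-connection block: push-pull x hyperbolic."""
    defaults = dict(
        weight_functions={
            "f1": ConnectorFunctionSpec("V1PushPull",
                                        {"or_sigma": 0.26, "phase_sigma": 0.52}),
            "f2": ConnectorFunctionSpec("Hyperbolic",
                                        {"theta": 207.76, "alpha": 0.013944}),
        },
        weight_expression="f1*f2",
        delay_expression="2",
        base_weight=0.108,
        num_samples=72,
        target_synapses="excitatory",
        short_term_plasticity=TMParams(U=0.5, tau_rec=1100.0, tau_fac=50.0,
                                       tau_psc=1.5),
    )
    defaults.update(kw)
    return ModularConnectorSpec(**defaults)


class TestSampling:
    def make_sheets(self, rng, n=400):
        pos = rng.uniform(-500, 500, size=(n, 2))
        ori = rng.uniform(0, np.pi, n)
        ph = rng.uniform(0, 2 * np.pi, n)
        a = toy_sheet("V1_Exc_L4", pos, ori, ph)
        pos2 = rng.uniform(-500, 500, size=(n, 2))
        b = toy_sheet("V1_Inh_L4", pos2, rng.uniform(0, np.pi, n),
                      rng.uniform(0, 2 * np.pi, n))
        return a, b

    def test_every_target_gets_num_samples_synapses(self, rng):
        src, tgt = self.make_sheets(rng)
        conn = sample_connections(lateral_spec(), src, tgt, rng)
        counts = np.bincount(conn.target, minlength=tgt.size)
        assert np.all(counts == 72)
        assert len(conn) == 72 * tgt.size

    def test_constant_delay_expression_exact(self, rng):
        src, tgt = self.make_sheets(rng, n=50)
        conn = sample_connections(lateral_spec(), src, tgt, rng)
        assert np.all(conn.delay == 2.0)
        assert np.all(conn.weight == 0.108)

    def test_single_nonzero_source_takes_all_samples(self, rng):
        src = toy_sheet("A", [[0.0, 0.0]])
        tgt = toy_sheet("B", [[10.0, 0.0], [20.0, 0.0]])
        spec = ModularConnectorSpec(
            weight_functions={"f1": ConnectorFunctionSpec("Constant", {"value": 1.0})},
            weight_expression="f1", base_weight=0.1, num_samples=10,
        )
        conn = sample_connections(spec, src, tgt, rng)
        assert np.all(conn.source == 0)

    def test_all_zero_distribution_names_target(self, rng):
        src = toy_sheet("A", [[0.0, 0.0]])
        tgt = toy_sheet("B", [[10.0, 0.0]])
        spec = ModularConnectorSpec(
            weight_functions={"f1": ConnectorFunctionSpec("Constant", {"value": 0.0})},
            weight_expression="f1", base_weight=0.1, num_samples=5,
        )
        with pytest.raises(ConnectorError, match="target neuron 0"):
            sample_connections(spec, src, tgt, rng)

    def test_uniform_sampling_chi_square(self, rng):
        src = toy_sheet("A", np.zeros((10, 2)))
        tgt = toy_sheet("B", [[0.0, 0.0]])
        spec = ModularConnectorSpec(
            weight_functions={"f1": ConnectorFunctionSpec("Constant", {"value": 3.0})},
            weight_expression="f1", base_weight=0.1, num_samples=100_000,
        )
        conn = sample_connections(spec, src, tgt, rng)
        counts = np.bincount(conn.source, minlength=10)
        expected = len(conn) / 10
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 9) > 0.01

    def test_empirical_frequencies_match_brute_force_probabilities(self, rng):
        # 5-source toy: brute-force normalized clipped expression values
        # vs empirical frequencies, 3-sigma multinomial bounds
        src = toy_sheet("A", [[0, 0], [100, 0], [200, 0], [300, 0], [400, 0]],
                        orientation=[0.1, 0.2, 0.3, 0.4, 0.5],
                        phase=[0.0, 1.0, 2.0, 3.0, 4.0])
        tgt = toy_sheet("B", [[0.0, 0.0]], orientation=[0.3], phase=[2.0])
        spec = lateral_spec(num_samples=100_000)
        # independent oracle: evaluate the kernels directly
        d = np.linalg.norm(src.positions - tgt.positions[0], axis=1)
        raw = (pushpull_value(src.metadata["orientation"] - 0.3,
                              src.metadata["phase"] - 2.0, 0.26, 0.52, "excitatory")
               * hyperbolic_value(d, 207.76, 0.013944))
        p = np.clip(raw, 0, None)
        p = p / p.sum()
        conn = sample_connections(spec, src, tgt, rng)
        counts = np.bincount(conn.source, minlength=5)
        n = len(conn)
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * sigma + 1)
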