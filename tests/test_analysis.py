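"""Analyses: trial-averaged rates, CV of ISI, summaries, tuning curves."""

import math

import numpy as np
import pytest

from circuitbench.analysis import (
    isi_cv,
    population_summary,
    trial_averaged_firing_rate,
    tuning_curves,
)
from circuitbench.datastore import DataStore, PerNeuronValue
from circuitbench.simulator import RecordedSegment
from circuitbench.stimuli import (
    FULLFIELD_GRATING,
    GRATING_DISK,
    StimulusDescriptor,
)


def segment(sheet, stim_kw, trains, duration=1000.0):
    stim = StimulusDescriptor(**stim_kw, duration=duration)
    ids = np.array(sorted(trains), dtype=int)
    return RecordedSegment(
        sheet_name=sheet, stimulus=stim.identity(), spike_ids=ids,
        spike_trains={k: np.asarray(v, dtype=float) for k, v in trains.items()},
        t_stop=duration,
    )


def grating_kw(**kw):
    base = dict(kind=FULLFIELD_GRATING, orientation=0.0, contrast=100.0, trial=0)
    base.update(kw)
    return base


class TestTrialAveragedFiringRate:
    def test_rate_averages_trials(self):
        # 5 and 7 spikes over two 1 s trials -> 6 spikes/s
        store = DataStore()
        store.add_segment(segment("S", grating_kw(trial=0),
                                  {0: np.linspace(1, 900, 5)}))
        store.add_segment(segment("S", grating_kw(trial=1),
                                  {0: np.linspace(1, 900, 7)}))
        [pnv] = trial_averaged_firing_rate(store)
        assert pnv.value_for(0) == pytest.approx(6.0)
        assert pnv.value_name == "Firing rate"
        assert pnv.units == "spikes/s"
        assert pnv.analysis_algorithm == "TrialAveragedFiringRate"
        assert "trial" not in pnv.stimulus_id

    def test_silent_neuron_rate_zero(self):
        store = DataStore()
        store.add_segment(segment("S", grating_kw(), {0: [], 1: [100.0]}))
        [pnv] = trial_averaged_firing_rate(store)
        assert pnv.value_for(0) == 0.0

    def test_one_ads_per_stripped_identity(self):
        store = DataStore()
        for orientation in (0.0, math.pi / 2):
            for trial in range(10):
                store.add_segment(segment(
                    "S", grating_kw(orientation=orientation, trial=trial),
                    {0: [50.0 * trial + 1.0]}))
        out = trial_averaged_firing_rate(store)
        assert len(out) == 2
        assert len(store.ads) == 2

    def test_permutation_invariant_over_trials(self):
        trains = [{0: np.linspace(1, 900, k + 2)} for k in range(4)]
        rates = []
        for order in ([0, 1, 2, 3], [3, 1, 0, 2]):
            store = DataStore()
            for pos, trial in enumerate(order):
                store.add_segment(segment("S", grating_kw(trial=trial),
                                          trains[trial]))
            [pnv] = trial_averaged_firing_rate(store)
            rates.append(pnv.value_for(0))
        assert rates[0] == rates[1]

    def test_spike_count_conservation(self):
        store = DataStore()
        total = 0
        for trial in range(3):
            n = 4 + trial
            total += n
            store.add_segment(segment("S", grating_kw(trial=trial),
                                      {0: np.linspace(1, 900, n)}))
        [pnv] = trial_averaged_firing_rate(store)
        # sum over neurons of rate * n_trials * duration == total spikes
        assert pnv.value_for(0) * 3 * 1.0 == pytest.approx(total)

    def test_inconsistent_recorded_durations_rejected(self):
        # same stimulus identity but mismatched recorded extents
        store = DataStore()
        a = segment("S", grating_kw(trial=0), {0: [1.0]})
        b = segment("S", grating_kw(trial=1), {0: [1.0]})
        b.t_stop = 500.0
        store.add_segment(a)
        store.add_segment(b)
        with pytest.raises(ValueError, match="duration"):
            trial_averaged_firing_rate(store)


class TestIsiCv:
    def test_periodic_train_cv_zero(self):
        assert isi_cv(np.arange(0, 1000, 10.0)) == pytest.approx(0.0)

    def test_poisson_train_cv_squared_near_one(self):
        rng = np.random.default_rng(3)
        train = np.cumsum(rng.exponential(1.0, size=10_000))
        cv = isi_cv(train)
        assert cv * cv == pytest.approx(1.0, abs=0.05)

    def test_short_train_excluded(self):
        assert isi_cv(np.array([1.0, 2.0])) is None


class TestPopulationSummary:
    def test_mean_rate_over_neurons(self):
        store = DataStore()
        store.add_ads(PerNeuronValue(
            identifier="PerNeuronValue", analysis_algorithm="TrialAveragedFiringRate",
            sheet_name="S", neuron_ids=np.array([0, 1]),
            values=np.array([4.0, 6.0]), value_name="Firing rate",
            units="spikes/s"))
        sv = population_summary(store, "mean_rate")
        assert sv.value == pytest.approx(5.0)
        assert sv.value_name == "Mean(firing rate)"

    def test_cv2_value_name(self):
        rng = np.random.default_rng(0)
        store = DataStore()
        train = np.cumsum(rng.exponential(10.0, 500))
        store.add_segment(segment("S", grating_kw(), {0: train},
                                  duration=float(train[-1] + 1)))
        sv = population_summary(store, "mean_cv2")
        assert sv.value_name == "Mean(CV of ISI squared)"
        assert sv.value == pytest.approx(1.0, abs=0.3)

    def test_empty_selection_errors(self):
        store = DataStore()
        with pytest.raises(ValueError):
            population_summary(store, "mean_rate")
        store.add_segment(segment("S", grating_kw(), {0: [1.0, 2.0]}))
        with pytest.raises(ValueError):
            population_summary(store, "mean_cv2")  # too few ISIs everywhere


class TestTuningCurves:
    def rate_ads(self, store, stim_kw, value):
        stim = StimulusDescriptor(**stim_kw, duration=1000.0)
        from circuitbench.identities import strip_params
        store.add_ads(PerNeuronValue(
            identifier="PerNeuronValue", analysis_algorithm="TrialAveragedFiringRate",
            sheet_name="S", stimulus_id=strip_params(stim.identity(), ["trial"]),
            neuron_ids=np.array([0]), values=np.array([value]),
            value_name="Firing rate", units="spikes/s"))

    def test_size_tuning_three_points(self):
        store = DataStore()
        for size, rate in zip((0.5, 1.0, 2.0), (3.0, 8.0, 5.0)):
            self.rate_ads(store, dict(kind=GRATING_DISK, size=size), rate)
        curves = tuning_curves(store, "size", [0])
        [(x, y)] = list(curves[0].values())
        assert np.array_equal(x, [0.5, 1.0, 2.0])
        assert np.array_equal(y, [3.0, 8.0, 5.0])

    def test_contrast_response_ten_points(self):
        store = DataStore()
        contrasts = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        for c in contrasts:
            self.rate_ads(store, grating_kw(contrast=float(c)), float(c) / 10)
        curves = tuning_curves(store, "contrast", [0])
        [(x, y)] = list(curves[0].values())
        assert len(x) == 10
        assert np.array_equal(x, np.array(contrasts, dtype=float))

    def test_mixed_stimulus_kinds_rejected(self):
        store = DataStore()
        self.rate_ads(store, dict(kind=GRATING_DISK, size=1.0), 1.0)
        self.rate_ads(store, grating_kw(), 2.0)
        with pytest.raises(ValueError, match="kind"):
            tuning_curves(store, "contrast", [0])

    def test_no_matching_ads_rejected(self):
        with pytest.raises(ValueError):
            tuning_curves(DataStore(), "size", [0])
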