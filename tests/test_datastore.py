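"""Datastore: views, the query algebra, persistence."""

import math

import numpy as np
import pytest

from circuitbench.datastore import (
    DataStore,
    PerNeuronValue,
    SingleValue,
    load,
    param_filter_query,
    partition_by_stimulus,
    save,
    view_union,
)
from circuitbench.simulator import RecordedSegment
from circuitbench.stimuli import FULLFIELD_GRATING, StimulusDescriptor


def make_segment(sheet="V1_Exc_L4", orientation=0.0, trial=0, contrast=100.0,
                 duration=1000.0, trains=None):
    stim = StimulusDescriptor(FULLFIELD_GRATING, duration=duration, trial=trial,
                              orientation=orientation, contrast=contrast)
    trains = trains if trains is not None else {0: np.array([10.0, 20.0])}
    ids = np.array(sorted(trains), dtype=int)
    return RecordedSegment(
        sheet_name=sheet, stimulus=stim.identity(), spike_ids=ids,
        spike_trains={k: np.asarray(v, dtype=float) for k, v in trains.items()},
        analog_ids=np.array([0]),
        analog={"v": np.linspace(-70, -60, 10).reshape(10, 1)},
        t_stop=duration,
    )


@pytest.fixture
def populated_store():
    store = DataStore("test model")
    for orientation in (0.0, math.pi / 2):
        for trial in range(10):
            store.add_segment(make_segment(orientation=orientation, trial=trial))
    store.add_segment(make_segment(sheet="V1_Inh_L4"))
    store.add_ads(PerNeuronValue(
        identifier="PerNeuronValue", analysis_algorithm="TrialAveragedFiringRate",
        sheet_name="V1_Exc_L4", neuron_ids=np.array([0, 1]),
        values=np.array([4.0, 6.0]), value_name="Firing rate", units="spikes/s"))
    store.add_ads(SingleValue(
        identifier="SingleValue", analysis_algorithm="PopulationSummary",
        sheet_name="V1_Inh_L4", value=5.0, value_name="Mean(firing rate)",
        units="spikes/s"))
    return store


class TestAppend:
    def test_counts_reflect_additions(self):
        store = DataStore()
        for _ in range(3):
            store.add_segment(make_segment())
        assert len(store.segments) == 3

    def test_views_are_read_only(self, populated_store):
        view = populated_store.full_view()
        with pytest.raises(TypeError):
            view.add_segment(make_segment())
        with pytest.raises(TypeError):
            view.add_ads(SingleValue(identifier="SingleValue",
                                     analysis_algorithm="x", value=1.0))

    def test_ads_requires_identifier(self, populated_store):
        sv = SingleValue(identifier="SingleValue", analysis_algorithm="x", value=1.0)
        sv.identifier = ""
        with pytest.raises(ValueError):
            populated_store.add_ads(sv)


class TestParamFilterQuery:
    def test_sheet_name_filters_segments_and_ads(self, populated_store):
        view = param_filter_query(populated_store, sheet_name=["V1_Exc_L4"])
        assert all(s.sheet_name == "V1_Exc_L4" for s in view.segments)
        assert len(view.segments) == 20
        assert all(a.sheet_name == "V1_Exc_L4" for a in view.ads)

    def test_stimulus_parameter_criteria(self, populated_store):
        view = param_filter_query(populated_store,
                                  st_name=FULLFIELD_GRATING, st_orientation=0)
        assert len(view.segments) == 11  # 10 exc trials + 1 inh segment
        assert all(s.stimulus["orientation"] == 0.0 for s in view.segments)

    def test_empty_criteria_is_identity(self, populated_store):
        full = populated_store.full_view()
        view = param_filter_query(full)
        assert view.segment_indices == full.segment_indices
        assert view.ads_indices == full.ads_indices

    def test_idempotence(self, populated_store):
        v1 = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        v2 = param_filter_query(v1, sheet_name="V1_Exc_L4")
        assert v1.segment_indices == v2.segment_indices
        assert v1.ads_indices == v2.ads_indices

    def test_commutativity_of_independent_criteria(self, populated_store):
        a = param_filter_query(param_filter_query(populated_store,
                                                  sheet_name="V1_Exc_L4"),
                               st_orientation=0)
        b = param_filter_query(param_filter_query(populated_store,
                                                  st_orientation=0),
                               sheet_name="V1_Exc_L4")
        assert a.segment_indices == b.segment_indices

    def test_objects_lacking_parameter_excluded(self, populated_store):
        view = param_filter_query(populated_store, value_name="Firing rate")
        assert len(view.ads) == 1
        assert isinstance(view.ads[0], PerNeuronValue)

    def test_views_share_backing_arrays(self, populated_store):
        view = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        assert view.segments[0] is populated_store.segments[0]
        assert view.segments[0].analog["v"] is populated_store.segments[0].analog["v"]


class TestPartition:
    def test_group_by_stripped_identity(self, populated_store):
        exc = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        groups = partition_by_stimulus(exc, except_params=["trial"])
        assert len(groups) == 2
        assert all(len(g.segments) == 10 for g in groups)

    def test_except_all_parameters_single_group(self, populated_store):
        exc = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        names = exc.segments[0].stimulus.param_names
        groups = partition_by_stimulus(exc, except_params=list(names))
        assert len(groups) == 1

    def test_except_nothing_one_group_per_identity(self, populated_store):
        exc = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        groups = partition_by_stimulus(exc, except_params=[])
        assert len(groups) == 20


class TestUnion:
    def test_union_of_disjoint_sheets(self, populated_store):
        a = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        b = param_filter_query(populated_store, sheet_name="V1_Inh_L4")
        u = view_union(a, b)
        assert len(u.segments) == 21

    def test_union_with_self_is_self(self, populated_store):
        a = param_filter_query(populated_store, sheet_name="V1_Exc_L4")
        u = view_union(a, a)
        assert u.segment_indices == a.segment_indices

    def test_union_of_complementary_orientations(self, populated_store):
        a = param_filter_query(populated_store, st_orientation=0)
        b = param_filter_query(populated_store, st_orientation=math.pi / 2)
        grating = param_filter_query(populated_store, st_name=FULLFIELD_GRATING)
        u = view_union(a, b)
        assert u.segment_indices == grating.segment_indices

    def test_union_across_stores_rejected(self, populated_store):
        other = DataStore()
        other.add_segment(make_segment())
        with pytest.raises(ValueError):
            view_union(populated_store.full_view(), other.full_view())


class TestPersistence:
    def test_round_trip_bit_exact(self, populated_store, tmp_path):
        save(populated_store, tmp_path / "store")
        back = load(tmp_path / "store")
        assert len(back.segments) == len(populated_store.segments)
        for a, b in zip(populated_store.segments, back.segments):
            assert a.sheet_name == b.sheet_name
            assert str(a.stimulus) == str(b.stimulus)
            for i in a.spike_ids:
                assert np.array_equal(a.spike_train(i), b.spike_train(i))
            for var in a.analog:
                assert np.array_equal(a.analog[var], b.analog[var])
        assert len(back.ads) == len(populated_store.ads)
        pnv_a = populated_store.ads[0]
        pnv_b = back.ads[0]
        assert np.array_equal(pnv_a.values, pnv_b.values)
        assert back.ads[1].value == populated_store.ads[1].value

    def test_appending_analysis_after_load(self, populated_store, tmp_path):
        save(populated_store, tmp_path / "store")
        back = load(tmp_path / "store")
        n_seg = len(back.segments)
        back.add_ads(SingleValue(identifier="SingleValue",
                                 analysis_algorithm="later", value=2.0,
                                 value_name="x"))
        assert len(back.segments) == n_seg
        assert len(back.ads) == len(populated_store.ads) + 1

    def test_missing_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load(tmp_path / "nowhere")

    def test_version_mismatch_rejected(self, populated_store, tmp_path):
        import json
        save(populated_store, tmp_path / "store")
        index = json.loads((tmp_path / "store" / "index.json").read_text())
        index["format_version"] = 999
        (tmp_path / "store" / "index.json").write_text(json.dumps(index))
        with pytest.raises(ValueError, match="version"):
            load(tmp_path / "store")
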