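"""Metadata-rich datastore: recordings, analysis products, and queries.

The store keeps two append-only lists — recorded segments and analysis
data structures (ADS) — plus block metadata.  Queries never copy raw
arrays: a :class:`DataStoreView` is an index subset over the backing
store, and ``param_filter_query`` composes such views.

Query semantics: ``sheet_name`` matches both segments and ADS; ``st_<p>``
keys match parameter ``p`` of the attached stimulus identity (``st_name``
the stimulus kind name); any other key matches declared ADS parameters
(``value_name``, ``analysis_algorithm``, ...).  List values mean
membership (OR); objects lacking a queried parameter are excluded.

On disk a store is a directory with a JSON index (identity strings and
metadata, diff-able) plus one ``.npz`` array container per segment; the
round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np

from .identities import (
    FLOAT_TOL,
    Identity,
    identity_from_string,
    identity_to_string,
    strip_params,
)
from .simulator import RecordedSegment

__all__ = [
    "DataStore",
    "DataStoreView",
    "AnalysisDataStructure",
    "PerNeuronValue",
    "SingleValue",
    "param_filter_query",
    "partition_by_stimulus",
    "view_union",
    "save",
    "load",
]

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Analysis data structures
# ---------------------------------------------------------------------------

@dataclass
class AnalysisDataStructure:
    """Base ADS: every field here is a declared, filterable parameter."""

    identifier: str
    analysis_algorithm: str
    sheet_name: str | None = None
    neuron: int | None = None
    stimulus_id: Identity | None = None

    def declared_params(self) -> dict[str, Any]:
        return {
            "identifier": self.identifier,
            "analysis_algorithm": self.analysis_algorithm,
            "sheet_name": self.sheet_name,
            "neuron": self.neuron,
        }


@dataclass
class PerNeuronValue(AnalysisDataStructure):
    """One scalar per neuron, with a value name, units and optional period."""

    neuron_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    value_name: str = ""
    units: str = "dimensionless"
    period: float | None = None

    def __post_init__(self) -> None:
        self.identifier = "PerNeuronValue"
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.neuron_ids.shape[0] != self.values.shape[0]:
            raise ValueError("neuron_ids and values must have equal length")
        if self.period is not None:
            self.values = np.mod(self.values, self.period)

    def declared_params(self) -> dict[str, Any]:
        out = super().declared_params()
        out.update(value_name=self.value_name, units=self.units, period=self.period)
        return out

    def value_for(self, neuron: int) -> float:
        idx = np.flatnonzero(self.neuron_ids == neuron)
        if idx.size == 0:
            raise KeyError(neuron)
        return float(self.values[idx[0]])


@dataclass
class SingleValue(AnalysisDataStructure):
    """A single scalar with a value name and units."""

    value: float = 0.0
    value_name: str = ""
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.identifier = "SingleValue"
        if not np.isfinite(self.value):
            raise ValueError("SingleValue must be finite")

    def declared_params(self) -> dict[str, Any]:
        out = super().declared_params()
        out.update(value_name=self.value_name, units=self.units)
        return out


# ---------------------------------------------------------------------------
# Store and views
# ---------------------------------------------------------------------------

class DataStore:
    """The backing store; append-only through the public interface."""

    def __init__(self, model_name: str = ""):
        self.model_name = model_name
        self._segments: list[RecordedSegment] = []
        self._ads: list[AnalysisDataStructure] = []
        self.experiment_log: list[str] = []

    # internal accessors used by views
    @property
    def segments(self) -> list[RecordedSegment]:
        return self._segments

    @property
    def ads(self) -> list[AnalysisDataStructure]:
        return self._ads

    def add_segment(self, seg: RecordedSegment) -> None:
        self._segments.append(seg)

    def add_ads(self, ads: AnalysisDataStructure) -> None:
        if not ads.identifier:
            raise ValueError("ADS must carry an identifier")
        self._ads.append(ads)

    def full_view(self) -> "DataStoreView":
        return DataStoreView(self, tuple(range(len(self._segments))),
                             tuple(range(len(self._ads))))

    def view(self) -> "DataStoreView":
        return self.full_view()


class DataStoreView:
    """Read-only index subset of a backing :class:`DataStore`."""

    def __init__(self, store: DataStore, segment_idx: tuple[int, ...],
                 ads_idx: tuple[int, ...]):
        self._store = store
        self._segment_idx = tuple(segment_idx)
        self._ads_idx = tuple(ads_idx)

    @property
    def store(self) -> DataStore:
        return self._store

    @property
    def segments(self) -> list[RecordedSegment]:
        return [self._store.segments[i] for i in self._segment_idx]

    @property
    def ads(self) -> list[AnalysisDataStructure]:
        return [self._store.ads[i] for i in self._ads_idx]

    @property
    def segment_indices(self) -> tuple[int, ...]:
        return self._segment_idx

    @property
    def ads_indices(self) -> tuple[int, ...]:
        return self._ads_idx

    def add_segment(self, seg) -> None:
        raise TypeError("DataStoreView is read-only; add to the backing DataStore")

    def add_ads(self, ads) -> None:
        raise TypeError("DataStoreView is read-only; add to the backing DataStore")

    def __len__(self) -> int:
        return len(self._segment_idx) + len(self._ads_idx)


def _as_view(ds: DataStore | DataStoreView) -> DataStoreView:
    return ds.full_view() if isinstance(ds, DataStore) else ds


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _scalar_eq(a: Any, b: Any) -> bool:
    if isinstance(a, (int, float)) and isinstance(b, (int, float)) \
            and not isinstance(a, bool) and not isinstance(b, bool):
        return abs(float(a) - float(b)) <= FLOAT_TOL
    return a == b


def _matches_options(value: Any, wanted: Any) -> bool:
    options = wanted if isinstance(wanted, (list, tuple)) else [wanted]
    return any(_scalar_eq(value, opt) for opt in options)


def _segment_matches(seg: RecordedSegment, criteria: Mapping[str, Any]) -> bool:
    from .identities import matches as id_matches

    for key, wanted in criteria.items():
        if key == "sheet_name":
            if not _matches_options(seg.sheet_name, wanted):
                return False
        elif key.startswith("st_"):
            if seg.stimulus is None:
                return False
            param = key[3:]
            if param == "name":
                if not _matches_options(seg.stimulus.kind, wanted):
                    return False
            elif not id_matches(seg.stimulus,
                                {param: list(wanted) if isinstance(wanted, (list, tuple))
                                 else wanted}):
                return False
        # other keys are ADS-only; segments are tested on sheet_name / st_* only
    return True


def _ads_matches(ads: AnalysisDataStructure, criteria: Mapping[str, Any]) -> bool:
    from .identities import matches as id_matches

    declared = ads.declared_params()
    for key, wanted in criteria.items():
        if key.startswith("st_"):
            if ads.stimulus_id is None:
                return False
            param = key[3:]
            if param == "name":
                if not _matches_options(ads.stimulus_id.kind, wanted):
                    return False
            elif not id_matches(ads.stimulus_id,
                                {param: list(wanted) if isinstance(wanted, (list, tuple))
                                 else wanted}):
                return False
        else:
            if key not in declared or declared[key] is None:
                return False
            if not _matches_options(declared[key], wanted):
                return False
    return True


def param_filter_query(dsv: DataStore | DataStoreView, **criteria: Any) -> DataStoreView:
    """Filter a store or view by metadata criteria; returns a view."""
    view = _as_view(dsv)
    seg_keys = {k: v for k, v in criteria.items()
                if k == "sheet_name" or k.startswith("st_")}
    seg_idx = tuple(i for i in view.segment_indices
                    if _segment_matches(view.store.segments[i], seg_keys))
    ads_idx = tuple(i for i in view.ads_indices
                    if _ads_matches(view.store.ads[i], criteria))
    return DataStoreView(view.store, seg_idx, ads_idx)


def partition_by_stimulus(dsv: DataStore | DataStoreView,
                          except_params: Iterable[str] = ()) -> list[DataStoreView]:
    """Group segments by their stimulus identity stripped of
    ``except_params``; deterministic order (sorted identity strings)."""
    view = _as_view(dsv)
    except_params = list(except_params)
    groups: dict[str, list[int]] = {}
    for i in view.segment_indices:
        seg = view.store.segments[i]
        if seg.stimulus is None:
            raise ValueError("partition_by_stimulus: segment without a stimulus identity")
        strippable = [p for p in except_params if p in seg.stimulus]
        key = identity_to_string(strip_params(seg.stimulus, strippable))
        groups.setdefault(key, []).append(i)
    return [DataStoreView(view.store, tuple(groups[k]), ())
            for k in sorted(groups)]


def view_union(a: DataStoreView, b: DataStoreView) -> DataStoreView:
    """Index-set union of two views over the same backing store."""
    if a.store is not b.store:
        raise ValueError("cannot union views over different backing stores")
    seg = tuple(sorted(set(a.segment_indices) | set(b.segment_indices)))
    ads = tuple(sorted(set(a.ads_indices) | set(b.ads_indices)))
    return DataStoreView(a.store, seg, ads)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _seg_filename(i: int) -> str:
    return f"segment_{i:06d}.npz"


def save(store: DataStore, directory: str | Path) -> None:
    """Write the store to ``directory`` (JSON index + npz per segment)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "model_name": store.model_name,
        "experiment_log": store.experiment_log,
        "segments": [],
        "ads": [],
    }
    for i, seg in enumerate(store.segments):
        arrays: dict[str, np.ndarray] = {
            "spike_ids": seg.spike_ids,
            "analog_ids": seg.analog_ids,
        }
        for j, nid in enumerate(sorted(seg.spike_trains)):
            arrays[f"train_{nid}"] = seg.spike_trains[nid]
        for var, arr in seg.analog.items():
            arrays[f"analog_{var}"] = arr
        np.savez(directory / _seg_filename(i), **arrays)
        index["segments"].append({
            "file": _seg_filename(i),
            "sheet_name": seg.sheet_name,
            "stimulus": identity_to_string(seg.stimulus) if seg.stimulus else None,
            "t_start": seg.t_start,
            "t_stop": seg.t_stop,
            "record_period": seg.record_period,
            "annotations": seg.annotations,
        })
    for ads in store.ads:
        entry: dict[str, Any] = {
            "identifier": ads.identifier,
            "analysis_algorithm": ads.analysis_algorithm,
            "sheet_name": ads.sheet_name,
            "neuron": ads.neuron,
            "stimulus_id": identity_to_string(ads.stimulus_id) if ads.stimulus_id else None,
        }
        if isinstance(ads, PerNeuronValue):
            entry.update(
                kind="PerNeuronValue",
                neuron_ids=[int(n) for n in ads.neuron_ids],
                values=[float(v) for v in ads.values],
                value_name=ads.value_name, units=ads.units, period=ads.period,
            )
        elif isinstance(ads, SingleValue):
            entry.update(kind="SingleValue", value=float(ads.value),
                         value_name=ads.value_name, units=ads.units)
        else:
            raise TypeError(f"cannot persist ADS of type {type(ads).__name__}")
        index["ads"].append(entry)
    (directory / "index.json").write_text(json.dumps(index, indent=1), encoding="utf-8")


def load(directory: str | Path) -> DataStore:
    """Load a store saved by :func:`save`; bit-exact round trip."""
    directory = Path(directory)
    index_path = directory / "index.json"
    if not index_path.exists():
        raise FileNotFoundError(f"no datastore index at {index_path}")
    try:
        index = json.loads(index_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt datastore index at {index_path}: {exc}") from exc
    version = index.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported datastore format version {version!r}")
    store = DataStore(index.get("model_name", ""))
    store.experiment_log = list(index.get("experiment_log", []))
    for entry in index["segments"]:
        with np.load(directory / entry["file"]) as npz:
            spike_ids = npz["spike_ids"]
            analog_ids = npz["analog_ids"]
            trains = {}
            analog = {}
            for key in npz.files:
                if key.startswith("train_"):
                    trains[int(key[6:])] = npz[key]
                elif key.startswith("analog_"):
                    analog[key[7:]] = npz[key]
        store.add_segment(RecordedSegment(
            sheet_name=entry["sheet_name"],
            stimulus=identity_from_string(entry["stimulus"]) if entry["stimulus"] else None,
            spike_ids=spike_ids,
            spike_trains=trains,
            analog_ids=analog_ids,
            analog=analog,
            t_start=entry["t_start"],
            t_stop=entry["t_stop"],
            record_period=entry["record_period"],
            annotations=dict(entry.get("annotations", {})),
        ))
    for entry in index["ads"]:
        stim = identity_from_string(entry["stimulus_id"]) if entry["stimulus_id"] else None
        if entry["kind"] == "PerNeuronValue":
            store.add_ads(PerNeuronValue(
                identifier="PerNeuronValue",
                analysis_algorithm=entry["analysis_algorithm"],
                sheet_name=entry["sheet_name"], neuron=entry["neuron"],
                stimulus_id=stim,
                neuron_ids=np.array(entry["neuron_ids"], dtype=int),
                values=np.array(entry["values"], dtype=float),
                value_name=entry["value_name"], units=entry["units"],
                period=entry["period"],
            ))
        else:
            store.add_ads(SingleValue(
                identifier="SingleValue",
                analysis_algorithm=entry["analysis_algorithm"],
                sheet_name=entry["sheet_name"], neuron=entry["neuron"],
                stimulus_id=stim, value=entry["value"],
                value_name=entry["value_name"], units=entry["units"],
            ))
    return store
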