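"""Analyses producing typed analysis data structures.

Each analysis takes a datastore view, applies itself to the widest subset
of its contents it can, and appends its products (``PerNeuronValue`` /
``SingleValue``) back to the backing store, annotated with the stimulus
identity (stripped of ``trial``), sheet name, value name, units and the
algorithm name — so subsequent analyses and plots can find them through
the query system.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .datastore import (
    DataStore,
    DataStoreView,
    PerNeuronValue,
    SingleValue,
    param_filter_query,
    partition_by_stimulus,
)
from .identities import identity_to_string, strip_params

__all__ = [
    "trial_averaged_firing_rate",
    "isi_cv",
    "population_summary",
    "tuning_curves",
]


def _as_view(ds: DataStore | DataStoreView) -> DataStoreView:
    return ds.full_view() if isinstance(ds, DataStore) else ds


def trial_averaged_firing_rate(dsv: DataStore | DataStoreView) -> list[PerNeuronValue]:
    """Per-neuron firing rate, averaged over trials of the same stimulus.

    For each sheet and each stimulus identity stripped of ``trial``, the
    rate of a neuron is its total spike count over the trials divided by
    ``n_trials * duration`` (spikes/s).  One ``PerNeuronValue`` per group
    is appended to the backing store.
    """
    view = _as_view(dsv)
    out: list[PerNeuronValue] = []
    sheet_names = sorted({seg.sheet_name for seg in view.segments})
    for sheet_name in sheet_names:
        sheet_view = param_filter_query(view, sheet_name=sheet_name)
        for group in partition_by_stimulus(sheet_view, except_params=["trial"]):
            segs = group.segments
            durations = {seg.duration for seg in segs}
            if len(durations) != 1:
                raise ValueError("inconsistent durations within a trial group")
            duration_ms = durations.pop()
            if duration_ms <= 0:
                continue
            ids = segs[0].spike_ids
            counts = np.zeros(ids.size)
            for seg in segs:
                counts += np.array([seg.spike_train(i).size for i in ids], dtype=float)
            rates = counts / (len(segs) * duration_ms / 1000.0)
            stripped = strip_params(
                segs[0].stimulus,
                ["trial"] if "trial" in segs[0].stimulus else [],
            )
            pnv = PerNeuronValue(
                identifier="PerNeuronValue",
                analysis_algorithm="TrialAveragedFiringRate",
                sheet_name=sheet_name,
                stimulus_id=stripped,
                neuron_ids=ids,
                values=rates,
                value_name="Firing rate",
                units="spikes/s",
            )
            view.store.add_ads(pnv)
            out.append(pnv)
    return out


def isi_cv(spike_train: np.ndarray) -> float | None:
    """Coefficient of variation of inter-spike intervals.

    Population (n) denominator.  Trains with fewer than 3 spikes (2 ISIs)
    carry no variability estimate and return None; aggregates exclude them.
    """
    train = np.asarray(spike_train, dtype=float)
    if train.size < 3:
        return None
    isi = np.diff(train)
    mean = isi.mean()
    if mean == 0:
        return None
    return float(isi.std(ddof=0) / mean)


def population_summary(dsv: DataStore | DataStoreView, statistic: str,
                       sheet_name: str | None = None) -> SingleValue:
    """Population mean as a SingleValue.

    ``statistic`` is ``"mean_rate"`` (mean of the Firing-rate
    ``PerNeuronValue`` entries; value_name ``Mean(firing rate)``) or
    ``"mean_cv2"`` (mean over neurons and segments of the squared CV of
    ISI of each recorded spike train; ``Mean(CV of ISI squared)``).
    """
    view = _as_view(dsv)
    if sheet_name is not None:
        view = param_filter_query(view, sheet_name=sheet_name)
    if statistic == "mean_rate":
        values: list[float] = []
        for ads in view.ads:
            if isinstance(ads, PerNeuronValue) and ads.value_name == "Firing rate":
                values.extend(float(v) for v in ads.values)
        if not values:
            raise ValueError("no firing-rate values in the selection")
        result, name, units = float(np.mean(values)), "Mean(firing rate)", "spikes/s"
    elif statistic == "mean_cv2":
        cv2: list[float] = []
        for seg in view.segments:
            for i in seg.spike_ids:
                cv = isi_cv(seg.spike_train(i))
                if cv is not None:
                    cv2.append(cv * cv)
        if not cv2:
            raise ValueError("no spike train with >= 2 inter-spike intervals "
                             "in the selection")
        result, name, units = float(np.mean(cv2)), "Mean(CV of ISI squared)", "dimensionless"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    sv = SingleValue(
        identifier="SingleValue",
        analysis_algorithm="PopulationSummary",
        sheet_name=sheet_name,
        value=result,
        value_name=name,
        units=units,
    )
    view.store.add_ads(sv)
    return sv


def tuning_curves(dsv: DataStore | DataStoreView, parameter_name: str,
                  neurons: Iterable[int]) -> dict[int, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-neuron response curves along one stimulus parameter.

    Collates ``PerNeuronValue`` ADS over identities of a single stimulus
    kind that vary in ``parameter_name``; one curve per neuron per
    combination of the remaining parameters, x sorted ascending.

    Returns ``{neuron: {residual_identity_string: (x, y)}}``.
    """
    view = _as_view(dsv)
    pnvs = [ads for ads in view.ads
            if isinstance(ads, PerNeuronValue) and ads.stimulus_id is not None
            and parameter_name in ads.stimulus_id]
    if not pnvs:
        raise ValueError(f"no PerNeuronValue ADS with stimulus parameter "
                         f"{parameter_name!r} in the selection")
    kinds = {ads.stimulus_id.kind for ads in pnvs}
    if len(kinds) > 1:
        raise ValueError(f"tuning curves span multiple stimulus kinds: {sorted(kinds)}")
    out: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    groups: dict[str, list[PerNeuronValue]] = {}
    for ads in pnvs:
        key = identity_to_string(strip_params(ads.stimulus_id, [parameter_name]))
        groups.setdefault(key, []).append(ads)
    for neuron in neurons:
        neuron = int(neuron)
        curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for key, members in sorted(groups.items()):
            xs, ys = [], []
            for ads in members:
                try:
                    y = ads.value_for(neuron)
                except KeyError:
                    continue
                xs.append(float(ads.stimulus_id[parameter_name]))
                ys.append(y)
            if xs:
                order = np.argsort(xs)
                curves[key] = (np.asarray(xs)[order], np.asarray(ys)[order])
        out[neuron] = curves
    return out
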