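"""HDF5 / delimited-text containers for simulated data and statistics."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .fmri import RegionTimeSeries, TaskDesign
from .neural_mass import SimulatedTrajectory, StimulusProtocol
from .trial_stats import TrialMatrix

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_trial_matrix",
    "load_trial_matrix",
    "save_region_series",
    "load_region_series",
    "save_raster_tsv",
    "events_to_tsv",
    "events_from_tsv",
]


def save_trajectory(path, traj: SimulatedTrajectory, signal_type: str = "neural") -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("activity", data=traj.activity)
        h5.attrs["dt"] = traj.dt
        h5.attrs["signal_type"] = signal_type
        h5.attrs["onset"] = traj.protocol.onset
        h5.attrs["offset"] = traj.protocol.offset
        h5.attrs["amplitude"] = np.atleast_1d(traj.protocol.amplitude)


def load_trajectory(path) -> SimulatedTrajectory:
    with h5py.File(path, "r") as h5:
        protocol = StimulusProtocol(
            amplitude=np.asarray(h5.attrs["amplitude"]),
            onset=float(h5.attrs["onset"]),
            offset=float(h5.attrs["offset"]),
        )
        return SimulatedTrajectory(
            dt=float(h5.attrs["dt"]),
            times=h5["times"][()],
            activity=h5["activity"][()],
            seed=None,
            protocol=protocol,
        )


def save_trial_matrix(path, data: TrialMatrix) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rates", data=data.rates)
        h5.create_dataset("condition", data=np.asarray(data.condition, dtype="S"))
        h5.attrs["time_step"] = data.time_step
        grp = h5.create_group("epoch_masks")
        for name, mask in data.epoch_masks.items():
            grp.create_dataset(name, data=mask)


def load_trial_matrix(path) -> TrialMatrix:
    with h5py.File(path, "r") as h5:
        condition = np.array([c.decode() for c in h5["condition"][()]])
        masks = {name: ds[()].astype(bool) for name, ds in h5["epoch_masks"].items()}
        return TrialMatrix(
            rates=h5["rates"][()],
            condition=condition,
            epoch_masks=masks,
            time_step=float(h5.attrs["time_step"]),
        )


def save_region_series(path, series: RegionTimeSeries, signal_type: str = "bold") -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=series.values)
        h5.create_dataset("run_boundaries", data=np.asarray(series.run_boundaries))
        h5.attrs["sampling_interval"] = series.sampling_interval
        h5.attrs["signal_type"] = signal_type
        h5.create_dataset(
            "region_labels", data=np.asarray(series.region_labels, dtype="S"))


def load_region_series(path) -> RegionTimeSeries:
    with h5py.File(path, "r") as h5:
        return RegionTimeSeries(
            values=h5["values"][()],
            sampling_interval=float(h5.attrs["sampling_interval"]),
            run_boundaries=h5["run_boundaries"][()].tolist(),
            region_labels=[s.decode() for s in h5["region_labels"][()]],
        )


def save_raster_tsv(path, rasters) -> None:
    """Spike events as a tidy TSV: trial, neuron_id, time_s."""
    rows = []
    for t, (ids, times) in enumerate(rasters.trials):
        rows.append(pd.DataFrame({"trial": t, "neuron_id": ids, "time_s": times}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def events_to_tsv(path, design: TaskDesign) -> None:
    """BIDS-style events table (onset, duration, trial_type)."""
    design.events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def events_from_tsv(path, fir_lag: int = 25) -> TaskDesign:
    return TaskDesign(events=pd.read_csv(path, sep="\t"), fir_lag=fir_lag)
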