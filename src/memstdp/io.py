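"""Config files (YAML) and delimited-table exports."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .memristor import DeviceParams, VariationModel
from .neuron import NeuronParams
from .protocol import ProtocolConfig, SpikeSession
from .simulator import ExperimentResult, SimConfig
from .waveforms import PulseShape

__all__ = [
    "ExperimentSetup",
    "load_setup",
    "save_setup",
    "session_table",
    "trajectory_table",
    "events_table",
    "stdp_window_table",
    "population_table",
    "save_membrane_h5",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ExperimentSetup:
    """Bundle of the four config blocks an experiment needs."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    device: DeviceParams = field(default_factory=DeviceParams)
    variation: Optional[VariationModel] = None
    neuron: NeuronParams = field(default_factory=NeuronParams)
    sim: SimConfig = field(default_factory=SimConfig)


_SECTIONS = {
    "protocol": ProtocolConfig,
    "device": DeviceParams,
    "variation": VariationModel,
    "neuron": NeuronParams,
    "sim": SimConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "synchronized_rows" in data:
        data = {**data, "synchronized_rows": tuple(data["synchronized_rows"])}
    return cls(**data)


def load_setup(path: PathLike) -> ExperimentSetup:
    """Read an :class:`ExperimentSetup` from a YAML file; absent sections use defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw and raw[name] is not None:
            kwargs[name] = _build(cls, dict(raw[name]))
    return ExperimentSetup(**kwargs)


def save_setup(setup: ExperimentSetup, path: PathLike) -> None:
    doc = {}
    for name in _SECTIONS:
        value = getattr(setup, name)
        if value is not None:
            doc[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in dataclasses.asdict(value).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def pulse_shape_to_config(shape: PulseShape) -> dict:
    return {"segments": shape.to_triplets(), "baseline": shape.baseline}


def pulse_shape_from_config(doc: dict) -> PulseShape:
    return PulseShape.from_triplets(doc["segments"], baseline=doc.get("baseline", 0.0))


def session_table(session: SpikeSession) -> pd.DataFrame:
    return session.to_table()


def trajectory_table(result: ExperimentResult) -> pd.DataFrame:
    """(epoch, row, conductance_uS) long-form table of the trajectory."""
    n_epochs1, n_rows = result.g_trajectory.shape
    epoch, row = np.divmod(np.arange(n_epochs1 * n_rows), n_rows)
    return pd.DataFrame({
        "epoch": epoch,
        "row": row,
        "conductance_uS": result.g_trajectory.ravel(),
    })


def events_table(session: SpikeSession, result: ExperimentResult) -> pd.DataFrame:
    """Input spikes and post spikes merged into one (t_ms, type, row) table."""
    pre = session.to_table().rename(columns={"onset_ms": "t_ms", "row_index": "row"})
    pre["type"] = "pre"
    post = pd.DataFrame({
        "t_ms": result.post_spike_times,
        "row": -1,
        "type": "post",
    })
    out = pd.concat([pre, post], ignore_index=True)
    return out.sort_values("t_ms").reset_index(drop=True)[["t_ms", "type", "row"]]


def stdp_window_table(window: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(window, columns=["dt_ms", "dG_over_G0_percent"])


def population_table(devices: Sequence[DeviceParams]) -> pd.DataFrame:
    """(device_index, parameter, value) long-form table of a sampled population."""
    rows = []
    for i, d in enumerate(devices):
        for f in dataclasses.fields(d):
            rows.append((i, f.name, getattr(d, f.name)))
    return pd.DataFrame(rows, columns=["device_index", "parameter", "value"])


def save_membrane_h5(result: ExperimentResult, path: PathLike) -> None:
    """Store the membrane trace (and trajectory) in an HDF5 container."""
    import h5py

    if result.membrane_trace is None:
        raise ConfigurationError("result carries no membrane trace; "
                                 "run with record_membrane=True")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("membrane/t_ms", data=result.membrane_trace[0])
        fh.create_dataset("membrane/u_V", data=result.membrane_trace[1])
        fh.create_dataset("g_trajectory_uS", data=result.g_trajectory)
        fh.create_dataset("post_spike_times_ms", data=result.post_spike_times)
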