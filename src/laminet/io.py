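"""HDF5 serialization for epochs, tvMVAR models and connectivity tensors.

All containers round-trip through a single HDF5 file with labeled axes;
2-D slices of the 5-way tensor can be exported as CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor
from .preprocess import EpochSet
from .stok import TvMVARModel

__all__ = ["save_epochs", "load_epochs", "save_model", "load_model",
           "save_tensor", "load_tensor", "export_slice_csv"]


def _write_strings(group, name, values):
    group.create_dataset(name, data=np.array([str(v) for v in values],
                                             dtype=h5py.string_dtype()))


def _read_strings(group, name):
    return [v.decode() if isinstance(v, bytes) else str(v)
            for v in group[name][()]]


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("signals", data=epochs.signals)
        g.create_dataset("times", data=epochs.times)
        g.attrs["fs"] = epochs.fs
        g.attrs["condition"] = epochs.condition
        g.attrs["animal"] = epochs.animal
        _write_strings(g, "area", epochs.channels["area"])
        _write_strings(g, "layer", epochs.channels["layer"].fillna(""))
        g.create_dataset("depth", data=epochs.channels["depth"].to_numpy(float))


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        g = f["epochs"]
        layers = [l or None for l in _read_strings(g, "layer")]
        meta = pd.DataFrame({"area": _read_strings(g, "area"),
                             "layer": layers,
                             "depth": g["depth"][()]})
        return EpochSet(g["signals"][()], float(g.attrs["fs"]),
                        g["times"][()], meta,
                        condition=str(g.attrs["condition"]),
                        animal=str(g.attrs["animal"]))


def save_model(model: TvMVARModel, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("tvmvar")
        g.create_dataset("A", data=model.A)
        g.create_dataset("sigma", data=model.sigma)
        g.create_dataset("times", data=model.times)
        if model.sigma_t is not None:
            g.create_dataset("sigma_t", data=model.sigma_t)
        g.attrs.update({"p": model.p, "c": model.c, "fs": model.fs,
                        "burn_in": model.burn_in})
        _write_strings(g, "labels", model.labels)


def load_model(path) -> TvMVARModel:
    with h5py.File(path, "r") as f:
        g = f["tvmvar"]
        return TvMVARModel(
            A=g["A"][()], sigma=g["sigma"][()],
            sigma_t=g["sigma_t"][()] if "sigma_t" in g else None,
            p=int(g.attrs["p"]), c=float(g.attrs["c"]),
            fs=float(g.attrs["fs"]), times=g["times"][()],
            labels=_read_strings(g, "labels"),
            burn_in=int(g.attrs["burn_in"]))


def save_tensor(tensor: ConnectivityTensor, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("tensor")
        g.create_dataset("values", data=tensor.values)
        g.create_dataset("times", data=tensor.times)
        g.create_dataset("freqs", data=tensor.freqs)
        g.attrs["condition"] = tensor.condition
        _write_strings(g, "animals", tensor.animals)
        if tensor.unfolded:
            _write_strings(g, "layers", tensor.layers)
            _write_strings(g, "connections",
                           [f"{s}->{t}" for s, t in tensor.connections])
        elif tensor.channels is not None:
            _write_strings(g, "area", tensor.channels["area"])
            _write_strings(g, "layer", tensor.channels["layer"])


def load_tensor(path) -> ConnectivityTensor:
    with h5py.File(path, "r") as f:
        g = f["tensor"]
        kwargs = dict(values=g["values"][()], times=g["times"][()],
                      freqs=g["freqs"][()],
                      condition=str(g.attrs["condition"]),
                      animals=_read_strings(g, "animals"))
        if "connections" in g:
            kwargs["layers"] = _read_strings(g, "layers")
            kwargs["connections"] = [tuple(c.split("->"))
                                     for c in _read_strings(g, "connections")]
        elif "area" in g:
            kwargs["channels"] = pd.DataFrame({
                "area": _read_strings(g, "area"),
                "layer": _read_strings(g, "layer"),
                "depth": np.nan})
        return ConnectivityTensor(**kwargs)


def export_slice_csv(tensor: ConnectivityTensor, path, *,
                     source_layer: str, target_layer: str,
                     connection: tuple[str, str]) -> None:
    """Write one time × frequency slice of an unfolded tensor as CSV."""
    if not tensor.unfolded:
        raise ValueError("CSV export requires an unfolded group tensor")
    sl = tensor.layers.index(source_layer)
    tl = tensor.layers.index(target_layer)
    ci = tensor.connections.index(tuple(connection))
    df = pd.DataFrame(tensor.values[sl, tl, :, :, ci],
                      index=pd.Index(tensor.times, name="time_s"),
                      columns=pd.Index(tensor.freqs, name="freq_hz"))
    df.to_csv(Path(path))
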