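"""Unit-annotated, uniformly sampled simulation traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trace:
    """Uniformly sampled time series of model variables.

    `t` is in ms; `data` maps channel name to an array of equal length;
    `units` maps channel name to its unit string; `stim_times` records the
    onset of every delivered stimulus.
    """

    t: np.ndarray
    data: dict
    units: dict
    stim_times: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(
                    f"channel {name!r} has length {arr.shape}, "
                    f"expected {self.t.shape}")
            self.data[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __contains__(self, name: str) -> bool:
        return name in self.data

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    @property
    def channels(self) -> list:
        return list(self.data)

    def slice(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 <= t <= t1 (stim times filtered alike)."""
        m = (self.t >= t0) & (self.t <= t1)
        stim = self.stim_times[(self.stim_times >= t0)
                               & (self.stim_times <= t1)]
        return Trace(self.t[m], {k: v[m] for k, v in self.data.items()},
                     dict(self.units), stim)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t [ms]": self.t}
        for name, arr in self.data.items():
            cols[f"{name} [{self.units.get(name, '1')}]"] = arr
        return pd.DataFrame(cols)

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        t = None
        data, units = {}, {}
        for col in df.columns:
            name, _, unit = col.partition(" [")
            unit = unit.rstrip("]")
            if name == "t":
                t = df[col].to_numpy()
            else:
                data[name] = df[col].to_numpy()
                units[name] = unit
        if t is None:
            raise ValueError(f"{path}: no 't [ms]' column")
        return cls(t, data, units)

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=self.t)
            f["t"].attrs["unit"] = "ms"
            g = f.create_group("channels")
            for name, arr in self.data.items():
                d = g.create_dataset(name, data=arr)
                d.attrs["unit"] = self.units.get(name, "1")
            f.create_dataset("stim_times", data=self.stim_times)

    @classmethod
    def from_hdf5(cls, path) -> "Trace":
        import h5py
        with h5py.File(path, "r") as f:
            t = f["t"][:]
            data = {k: f["channels"][k][:] for k in f["channels"]}
            units = {k: f["channels"][k].attrs.get("unit", "1")
                     for k in f["channels"]}
            stim = f["stim_times"][:] if "stim_times" in f else None
        return cls(t, data, units,
                   stim if stim is not None else np.empty(0))


def concat(traces: list) -> Trace:
    """Concatenate consecutive traces (drops duplicated joint samples)."""
    if not traces:
        raise ValueError("no traces to concatenate")
    t = [traces[0].t]
    data = {k: [v] for k, v in traces[0].data.items()}
    stim = [traces[0].stim_times]
    for tr in traces[1:]:
        drop = 1 if (len(tr.t) and len(t[-1]) and
                     tr.t[0] <= t[-1][-1] + 1e-9) else 0
        t.append(tr.t[drop:])
        for k in data:
            data[k].append(tr.data[k][drop:])
        stim.append(tr.stim_times)
    return Trace(np.concatenate(t),
                 {k: np.concatenate(v) for k, v in data.items()},
                 dict(traces[0].units), np.concatenate(stim))


def write_trace(trace: Trace, path) -> None:
    """Write a trace; format chosen by extension (.csv or .h5/.hdf5)."""
    s = str(path)
    if s.endswith((".h5", ".hdf5")):
        trace.to_hdf5(path)
    else:
        trace.to_csv(path)


def read_trace(path) -> Trace:
    """Read a trace written by `write_trace`."""
    s = str(path)
    if s.endswith((".h5", ".hdf5")):
        return Trace.from_hdf5(path)
    return Trace.from_csv(path)
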