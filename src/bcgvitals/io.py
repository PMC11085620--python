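"""Readers and writers for the pipeline's file formats.

CSV carries signals (time_s, amplitude), R-R series, feature matrices
and metric reports; HDF5 carries signals, IMF sets and network
weights. CSV dialect: comma-separated, header row, '.' decimal, UTF-8.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import RRSeries, Signal
from .decomposition import IMFSet

__all__ = [
    "read_signal",
    "write_signal",
    "write_imfset",
    "read_imfset",
    "write_rr",
    "read_rr",
    "write_pca",
    "write_weights",
    "read_weights",
    "load_network",
    "write_json",
]


def write_signal(path, signal: Signal, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        frame = pd.DataFrame({"time_s": signal.times, "amplitude": signal.samples})
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# fs={signal.fs}\n")
            frame.to_csv(fh, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("signal", data=signal.samples)
            fh.create_dataset("fs", data=signal.fs)
    else:
        raise ValueError(f"unknown signal format: {fmt!r}")
    return path


def read_signal(path, fmt: str | None = None, fs: float | None = None) -> Signal:
    """Load a signal from CSV (time_s, amplitude) or HDF5 (/signal, /fs).

    The sampling rate comes from the HDF5 metadata, the CSV ``# fs=``
    header line, the time column spacing, or the ``fs`` argument —
    in that order of preference. NaN/inf rows are rejected with their
    row number.
    """
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            return Signal(fh["signal"][...], float(fh["fs"][()]))
    if fmt != "csv":
        raise ValueError(f"unknown signal format: {fmt!r}")
    header_fs = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# fs="):
            header_fs = float(first.split("=", 1)[1])
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    bad = np.flatnonzero(~np.isfinite(frame.to_numpy(dtype=float)).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite value in CSV data row {int(bad[0])}")
    if header_fs is not None:
        use_fs = header_fs
    elif "time_s" in frame.columns and len(frame) > 1:
        dt = np.diff(frame["time_s"].to_numpy())
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time column is not uniformly sampled")
        use_fs = 1.0 / dt[0]
    elif fs is not None:
        use_fs = fs
    else:
        raise ValueError("sampling rate not recoverable; pass fs (--fs on the CLI)")
    return Signal(frame["amplitude"].to_numpy(dtype=float), use_fs)


def write_imfset(path, dec: IMFSet, seed: int | None = None) -> Path:
    """IMF set to HDF5 (/imfs 2-D, /residue, /meta) or wide CSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            if len(dec):
                fh.create_dataset("imfs", data=np.vstack([c.samples for c in dec.imfs]))
            else:
                fh.create_dataset("imfs", data=np.empty((0, dec.residue.samples.size)))
            fh.create_dataset("residue", data=dec.residue.samples)
            meta = fh.create_group("meta")
            meta.attrs["method"] = dec.method
            meta.attrs["fs"] = dec.residue.fs
            meta.attrs["sift_counts"] = dec.sift_counts
            if seed is not None:
                meta.attrs["seed"] = seed
    else:
        cols = {f"imf_{i + 1}": c.samples for i, c in enumerate(dec.imfs)}
        cols["residue"] = dec.residue.samples
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# method={dec.method} fs={dec.residue.fs}\n")
            pd.DataFrame(cols).to_csv(fh, index=False)
    return path


def read_imfset(path) -> IMFSet:
    path = Path(path)
    if path.suffix not in (".h5", ".hdf5"):
        raise ValueError("IMF sets are read back from HDF5 only")
    with h5py.File(path, "r") as fh:
        fs = float(fh["meta"].attrs["fs"])
        imfs = [Signal(row, fs) for row in fh["imfs"][...]]
        return IMFSet(
            imfs=imfs,
            residue=Signal(fh["residue"][...], fs),
            sift_counts=list(fh["meta"].attrs.get("sift_counts", [])),
            method=str(fh["meta"].attrs["method"]),
        )


def write_rr(path, rr: RRSeries) -> Path:
    path = Path(path)
    beat = rr.beat_times_s if rr.beat_times_s is not None else np.concatenate(
        ([0.0], np.cumsum(rr.intervals_ms[:-1]) / 1000.0)
    )
    pd.DataFrame(
        {"beat_time_s": beat, "interval_ms": rr.intervals_ms, "valid": rr.valid_mask.astype(int)}
    ).to_csv(path, index=False)
    return path


def read_rr(path) -> RRSeries:
    frame = pd.read_csv(path)
    return RRSeries(
        intervals_ms=frame["interval_ms"].to_numpy(dtype=float),
        beat_times_s=frame["beat_time_s"].to_numpy(dtype=float),
        valid_mask=frame.get("valid", pd.Series(np.ones(len(frame)))).to_numpy(dtype=bool),
    )


def write_pca(path, red) -> Path:
    """PCA model to HDF5: /loadings, /center, /scales, /explained."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("loadings", data=red.components)
        fh.create_dataset("center", data=red.center)
        fh.create_dataset("scales", data=red.scales)
        fh.create_dataset("explained", data=red.explained_variance_fractions)
    return path


def write_weights(path, net) -> Path:
    """Framework-neutral HDF5 weight export: one group per parameter."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for i, p in enumerate(net.params()):
            fh.create_dataset(p.name or f"param_{i}", data=p.value)
        if net.x_mean is not None:
            fh.create_dataset("scaler/x_mean", data=net.x_mean)
            fh.create_dataset("scaler/x_std", data=net.x_std)
        fh.attrs["y_mean"] = net.y_mean
        fh.attrs["y_std"] = net.y_std
        fh.attrs["trained"] = net.trained
        from dataclasses import asdict

        fh.attrs["config"] = json.dumps(asdict(net.config))
    return path


def load_network(path):
    """Rebuild a network from a checkpoint's stored config and weights."""
    from .model import NetworkConfig, build_network

    with h5py.File(path, "r") as fh:
        config = NetworkConfig(**json.loads(fh.attrs["config"]))
    return read_weights(path, build_network(config))


def read_weights(path, net):
    """Load exported weights into a freshly built, shape-compatible net."""
    with h5py.File(path, "r") as fh:
        for i, p in enumerate(net.params()):
            p.value[...] = fh[p.name or f"param_{i}"][...]
        if "scaler/x_mean" in fh:
            net.x_mean = fh["scaler/x_mean"][...]
            net.x_std = fh["scaler/x_std"][...]
        net.y_mean = float(fh.attrs["y_mean"])
        net.y_std = float(fh.attrs["y_std"])
        net.trained = bool(fh.attrs["trained"])
    return net


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n", encoding="utf-8")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
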