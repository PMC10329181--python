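"""Readers and writers for the package's on-disk formats.

Coordinates are always stored in mm and times in us; every delimited text
file carries a leading comment line stating its units, because unit drift
is the dominant failure mode when exchanging calibration data.  Waveforms
and volumes use HDF5.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import PointSourceGrid, ToAMatrix
from .exceptions import ConfigError, InvalidInputError
from .reconstruction import Volume
from .toa import WaveformSet

__all__ = [
    "write_positions",
    "read_positions",
    "write_grid",
    "read_grid",
    "write_toas",
    "read_toas",
    "write_waveforms",
    "read_waveforms",
    "write_volume",
    "read_volume",
    "load_config",
]


def _read_table(path, required: list[str], all_numeric: bool = True) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several flavours here
        raise InvalidInputError(f"{path}: cannot parse as delimited text ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    if all_numeric:
        for col in required:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna()
            if bad.any():
                # +2: one header line plus 1-based numbering (comment lines
                # shift this, but the row content is quoted)
                rows = [f"line {i + 2} ({df[col].iloc[i]!r})" for i in np.flatnonzero(bad)[:5]]
                raise InvalidInputError(
                    f"{path}: non-numeric values in column {col!r}: {', '.join(rows)}"
                )
            df[col] = vals
    return df


def write_positions(path, positions, delays=None) -> None:
    """Write transducer coordinates: ``index,x_mm,y_mm,z_mm[,delay_us]``."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    data = {
        "index": np.arange(len(positions)),
        "x_mm": positions[:, 0],
        "y_mm": positions[:, 1],
        "z_mm": positions[:, 2],
    }
    if delays is not None:
        data["delay_us"] = np.asarray(delays, dtype=float)
    with open(path, "w") as fh:
        fh.write("# transducer coordinates in mm; delays in us\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def read_positions(path):
    """Read transducer coordinates; returns ``(positions, delays_or_None)``."""
    df = _read_table(path, ["index", "x_mm", "y_mm", "z_mm"])
    df = df.sort_values("index")
    pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    delays = df["delay_us"].to_numpy(float) if "delay_us" in df.columns else None
    return pos, delays


def write_grid(path, grid: PointSourceGrid) -> None:
    with open(path, "w") as fh:
        fh.write("# point-source positions in the stage frame, mm\n")
        pd.DataFrame(
            {
                "index": np.arange(len(grid)),
                "x_mm": grid.positions[:, 0],
                "y_mm": grid.positions[:, 1],
                "z_mm": grid.positions[:, 2],
            }
        ).to_csv(fh, index=False)


def read_grid(path) -> PointSourceGrid:
    df = _read_table(path, ["index", "x_mm", "y_mm", "z_mm"])
    return PointSourceGrid(df.sort_values("index")[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


def write_toas(path, toas: ToAMatrix) -> None:
    """Write a ToA table: ``source_index,transducer_index,toa_us,valid``."""
    M, N = toas.shape
    m, n = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    with open(path, "w") as fh:
        fh.write("# arrival times in us; valid is 0/1\n")
        pd.DataFrame(
            {
                "source_index": m.ravel(),
                "transducer_index": n.ravel(),
                "toa_us": toas.times.ravel(),
                "valid": toas.valid.ravel().astype(int),
            }
        ).to_csv(fh, index=False, float_format="%.9g")


def read_toas(path) -> ToAMatrix:
    df = _read_table(path, ["source_index", "transducer_index", "toa_us"], all_numeric=False)
    for col in ("source_index", "transducer_index", "valid"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    M = df["source_index"].max() + 1
    N = df["transducer_index"].max() + 1
    times = np.full((M, N), np.nan)
    valid = np.zeros((M, N), dtype=bool)
    times[df["source_index"], df["transducer_index"]] = pd.to_numeric(df["toa_us"], errors="coerce")
    if "valid" in df.columns:
        valid[df["source_index"], df["transducer_index"]] = df["valid"].astype(bool)
    else:
        valid = np.isfinite(times)
    times[~valid] = np.nan
    return ToAMatrix(times, valid)


def write_waveforms(path, waveforms: WaveformSet) -> None:
    """HDF5 layout: ``/waveforms`` (M x N x T, float32) with attributes
    ``sampling_rate_MHz`` and ``time_origin_us``; optional
    ``/source_positions_mm`` and ``/receive_delays_us`` datasets."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("waveforms", data=waveforms.samples.astype(np.float32))
        ds.attrs["sampling_rate_MHz"] = waveforms.sampling_rate
        ds.attrs["time_origin_us"] = waveforms.time_origin
        if waveforms.source_positions is not None:
            fh.create_dataset("source_positions_mm", data=waveforms.source_positions)
        if waveforms.receive_delays is not None:
            fh.create_dataset("receive_delays_us", data=waveforms.receive_delays)


def read_waveforms(path) -> WaveformSet:
    with h5py.File(path, "r") as fh:
        if "waveforms" not in fh:
            raise InvalidInputError(f"{path}: missing /waveforms dataset")
        ds = fh["waveforms"]
        for attr in ("sampling_rate_MHz", "time_origin_us"):
            if attr not in ds.attrs:
                raise InvalidInputError(f"{path}: /waveforms lacks attribute {attr}")
        return WaveformSet(
            samples=ds[...].astype(float),
            sampling_rate=float(ds.attrs["sampling_rate_MHz"]),
            time_origin=float(ds.attrs["time_origin_us"]),
            receive_delays=fh["receive_delays_us"][...] if "receive_delays_us" in fh else None,
            source_positions=fh["source_positions_mm"][...] if "source_positions_mm" in fh else None,
        )


def write_volume(path, volume: Volume) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("volume", data=volume.values)
        ds.attrs["origin_mm"] = volume.origin
        ds.attrs["spacing_mm"] = volume.spacing


def read_volume(path) -> Volume:
    with h5py.File(path, "r") as fh:
        if "volume" not in fh:
            raise InvalidInputError(f"{path}: missing /volume dataset")
        ds = fh["volume"]
        return Volume(ds[...], np.asarray(ds.attrs["origin_mm"]), np.asarray(ds.attrs["spacing_mm"]))


def load_config(path) -> dict:
    """Load a YAML configuration mapping."""
    with open(path) as fh:
        try:
            config = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return config
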