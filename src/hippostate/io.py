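"""Readers and writers for the pipeline's on-disk formats.

Traces and rasters live in HDF5 (with a delimited-text fallback); interval
sets, spike trains and per-unit metadata are tab-separated text. Text
numbers are printed to 9 significant digits, which is the round-trip
precision the formats guarantee.
"""

from __future__ import annotations

import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import HYPNOGRAM_EPOCH_S, EventRaster, IntervalSet, SignalTrace, SpikeTrain
from .errors import InvalidParameterError

_FMT = "%.9g"


# ----------------------------------------------------------------- traces

def write_trace_h5(path: str | Path, trace: SignalTrace, channel: str | None = None) -> None:
    """Append one channel to an HDF5 trace file (dataset per channel)."""
    name = channel or trace.label or "channel0"
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=trace.samples)
        ds.attrs["rate_hz"] = float(trace.rate)
        ds.attrs["units"] = trace.units
        ds.attrs["start_time_s"] = float(trace.start_time)


def read_trace_h5(path: str | Path, channel: str | None = None) -> SignalTrace:
    with h5py.File(path, "r") as f:
        names = list(f.keys())
        if not names:
            raise InvalidParameterError(f"{path}: no channels")
        name = channel or names[0]
        if name not in f:
            raise InvalidParameterError(f"{path}: no channel {name!r}")
        ds = f[name]
        return SignalTrace(
            samples=ds[()],
            rate=float(ds.attrs["rate_hz"]),
            start_time=float(ds.attrs.get("start_time_s", 0.0)),
            label=name,
            units=str(ds.attrs.get("units", "mV")),
        )


def write_trace_csv(path: str | Path, trace: SignalTrace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    df.to_csv(path, index=False, float_format=_FMT)


def read_trace_csv(path: str | Path, units: str = "mV", label: str = "") -> SignalTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise InvalidParameterError(f"{path}: need >= 2 samples to infer rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise InvalidParameterError(f"{path}: time column is not uniformly sampled")
    return SignalTrace(
        samples=df["value"].to_numpy(float),
        rate=1.0 / float(dt[0]),
        start_time=float(t[0]),
        label=label,
        units=units,
    )


# -------------------------------------------------------------- intervals

def write_intervals(path: str | Path, intervals: IntervalSet) -> None:
    df = pd.DataFrame(intervals.intervals, columns=["start_s", "end_s", "label"])
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_intervals(path: str | Path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t")
    return IntervalSet(
        [(float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()]
    )


def read_hypnogram(path: str | Path, epoch_s: float = HYPNOGRAM_EPOCH_S) -> IntervalSet:
    """Read a hypnogram, enforcing the scoring epoch grid.

    Vigilance scoring is done in fixed 5-s epochs, so every interval bound
    must be a multiple of ``epoch_s``; misaligned bounds are rejected rather
    than silently rounded.
    """
    ivs = read_intervals(path)
    for s, e, l in ivs:
        for bound in (s, e):
            if not math.isclose(bound / epoch_s, round(bound / epoch_s), abs_tol=1e-9):
                raise InvalidParameterError(
                    f"{path}: bound {bound} s is not a multiple of the {epoch_s}-s epoch"
                )
    return ivs


# ------------------------------------------------------------ spike trains

def write_spike_trains(
    spikes_path: str | Path, trains: list[SpikeTrain], units_path: str | Path | None = None
) -> None:
    rows = [(t.unit_id, time) for t in trains for time in t.times]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        spikes_path, sep="\t", index=False, float_format=_FMT
    )
    if units_path is not None:
        meta = pd.DataFrame(
            {
                "unit_id": [t.unit_id for t in trains],
                "isi_violation_frac": [t.isi_violation_frac for t in trains],
                "isolation_distance": [t.isolation_distance for t in trains],
                "unit_class": [t.unit_class or "" for t in trains],
            }
        )
        meta.to_csv(units_path, sep="\t", index=False, float_format=_FMT)


def read_spike_trains(
    spikes_path: str | Path, units_path: str | Path | None = None
) -> list[SpikeTrain]:
    df = pd.read_csv(spikes_path, sep="\t", dtype={"unit_id": str})
    meta = None
    if units_path is not None:
        meta = pd.read_csv(units_path, sep="\t", dtype={"unit_id": str}).set_index("unit_id")
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        kw = {}
        if meta is not None and uid in meta.index:
            row = meta.loc[uid]
            kw = dict(
                isi_violation_frac=float(row["isi_violation_frac"]),
                isolation_distance=float(row["isolation_distance"]),
                unit_class=(str(row["unit_class"]) or None)
                if isinstance(row["unit_class"], str) and row["unit_class"]
                else None,
            )
        # printed precision can collide adjacent times; keep strictly ascending
        times = np.unique(grp["time_s"].to_numpy(float))
        trains.append(SpikeTrain(unit_id=str(uid), times=times, **kw))
    return trains


# ---------------------------------------------------------------- rasters

def write_raster_h5(path: str | Path, raster: EventRaster) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("events", data=raster.events)
        ds.attrs["frame_rate_hz"] = float(raster.frame_rate)
        f.create_dataset(
            "cell_ids", data=np.array(raster.cell_ids, dtype=h5py.string_dtype())
        )


def read_raster_h5(path: str | Path) -> EventRaster:
    with h5py.File(path, "r") as f:
        events = f["events"][()]
        rate = float(f["events"].attrs["frame_rate_hz"])
        cell_ids = (
            [c.decode() if isinstance(c, bytes) else str(c) for c in f["cell_ids"][()]]
            if "cell_ids" in f
            else None
        )
    return EventRaster(events=events, frame_rate=rate, cell_ids=cell_ids)


def write_raster_csv(path: str | Path, raster: EventRaster) -> None:
    df = pd.DataFrame(raster.events, index=raster.cell_ids)
    df.index.name = "cell_id"
    df.to_csv(path, float_format=_FMT)


def read_raster_csv(path: str | Path, frame_rate: float = 10.0) -> EventRaster:
    df = pd.read_csv(path, index_col="cell_id")
    return EventRaster(
        events=df.to_numpy(float), frame_rate=frame_rate, cell_ids=[str(i) for i in df.index]
    )
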