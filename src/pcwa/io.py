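"""Trace and event-table readers/writers plus the serialisable run config.

Trace formats:

* ``tsv2col`` — two delimited columns (time, value), header auto-detected;
  the bin width is inferred from the median time step and must be uniform
  to 1e-6 relative.
* ``counts`` — a single column of counts plus an explicit ``dt``.
* ``hdf5`` — a ``/counts`` dataset with ``dt`` and ``t0`` attributes.

Event tables are delimited text with a stable column order and fixed
decimal formatting, so a saved run re-reads byte-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifiedEvent
from .cwt import CWTMap, Trace
from .detector import Event
from .errors import FormatError

__all__ = [
    "read_trace",
    "write_trace",
    "write_events",
    "read_events",
    "write_cwt_map",
    "RunConfig",
]

EVENT_COLUMNS = ["t", "scale", "coeff", "n_members", "t_adjusted", "n_peaks", "velocity"]


def read_trace(path, fmt: str = "tsv2col", dt: float | None = None) -> Trace:
    """Read a trace from disk; see module docstring for the formats."""
    path = Path(path)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if "counts" not in f:
                raise FormatError(f"{path}: no /counts dataset")
            counts = np.asarray(f["counts"], dtype=float)
            dt_file = float(f.attrs.get("dt", dt if dt is not None else 0.0))
            t0 = float(f.attrs.get("t0", 0.0))
        if dt_file <= 0:
            raise FormatError(f"{path}: missing dt attribute")
        return Trace(counts=counts, dt=dt_file, t0=t0)

    if fmt == "counts":
        if dt is None or dt <= 0:
            raise FormatError("counts format requires an explicit positive dt")
        try:
            counts = np.loadtxt(path, comments="#", ndmin=1)
        except ValueError:
            counts = np.loadtxt(path, comments="#", skiprows=1, ndmin=1)  # header row
        if counts.ndim != 1 or len(counts) == 0:
            raise FormatError(f"{path}: counts format needs one numeric column")
        return Trace(counts=counts, dt=dt)

    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                         skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise FormatError(f"{path}: empty or malformed file ({exc})") from None
    # header auto-detect: drop a first row that does not parse as numbers
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    df = df.astype(float)

    if fmt != "tsv2col":
        raise FormatError(f"unknown trace format {fmt!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: tsv2col needs two columns (time, value)")
    t = df.iloc[:, 0].to_numpy()
    counts = df.iloc[:, 1].to_numpy()
    steps = np.diff(t)
    dt_est = float(np.median(steps))
    if dt_est <= 0:
        raise FormatError(f"{path}: non-increasing time column")
    bad = np.flatnonzero(np.abs(steps - dt_est) > 1e-6 * dt_est)
    if len(bad):
        raise FormatError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 1} "
            f"(step {steps[bad[0]]:g}, expected {dt_est:g})"
        )
    return Trace(counts=counts, dt=dt_est, t0=float(t[0]))


def write_trace(trace: Trace, path) -> None:
    """Write a trace as two-column (time, counts) tab-separated text."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "counts": trace.counts})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def _events_frame(events) -> pd.DataFrame:
    rows = []
    for e in events:
        if isinstance(e, ClassifiedEvent):
            ev, vel = e.event, e.velocity
        else:
            ev, vel = e, None
        rows.append(
            {
                "t": ev.t,
                "scale": ev.scale,
                "coeff": ev.coeff,
                "n_members": ev.n_members,
                "t_adjusted": ev.t_adjusted,
                "n_peaks": ev.n_peaks,
                "velocity": np.nan if vel is None else vel,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values("t").reset_index(drop=True) if len(df) else df


def write_events(events, path) -> None:
    """Write an event table (header + one row per event, sorted by t)."""
    _events_frame(events).to_csv(Path(path), sep="\t", index=False, float_format="%.9f")


def read_events(path) -> list[Event]:
    """Read an event table written by :func:`write_events`."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = set(EVENT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        Event(
            t=float(r.t), scale=float(r.scale), coeff=float(r.coeff),
            n_members=int(r.n_members), t_adjusted=float(r.t_adjusted),
            n_peaks=int(r.n_peaks),
        )
        for r in df.itertuples()
    ]


def write_cwt_map(cmap: CWTMap, path) -> None:
    """Export a CWT map to HDF5 (/coeffs, /scales, dt and t0 attributes)."""
    import h5py

    with h5py.File(Path(path), "w") as f:
        f.create_dataset("coeffs", data=cmap.coeffs)
        f.create_dataset("scales", data=cmap.grid.scales)
        f.create_dataset("margins", data=cmap.margins)
        f.attrs["dt"] = cmap.dt
        f.attrs["t0"] = cmap.t0


@dataclass
class RunConfig:
    """A fully serialisable description of one detection run.

    A saved RunConfig plus the same input trace re-executes to identical
    outputs (all randomness lives in the simulator's seed).
    """

    wavelet: str = "ricker"
    msg_n: int = 7
    msg_sigma_plus: float = 0.18
    msg_alpha: float = 3.0
    morlet_cycles: float = 2.0
    scale_min: float = 1e-4
    scale_max: float = 1e-2
    n_scales: int = 100
    threshold: float = 0.0
    threshold_mode: str = "absolute"
    w: float = 1.0
    h: float = 1.0
    gap: float | None = None
    min_cluster_size: int = 3
    candidates: list[int] = field(default_factory=lambda: [6, 7, 8])
    pitch_um: float | None = None
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def wavelet_spec(self):
        from . import wavelets as wv

        if self.wavelet == "ricker":
            return wv.ricker_spec()
        if self.wavelet == "morlet":
            return wv.morlet_spec(center_cycles=self.morlet_cycles)
        if self.wavelet == "msg":
            return wv.msg_spec(self.msg_n, sigma_plus=self.msg_sigma_plus, alpha=self.msg_alpha)
        raise FormatError(f"unknown wavelet {self.wavelet!r}")

    def scale_grid(self):
        from .cwt import make_log_grid

        return make_log_grid(self.scale_min, self.scale_max, self.n_scales)

    def detector_config(self) -> "DetectorConfig":
        from .detector import DetectorConfig

        return DetectorConfig(
            threshold=self.threshold,
            w=self.w,
            h=self.h,
            gap=self.gap,
            min_cluster_size=self.min_cluster_size,
            threshold_mode=self.threshold_mode,  # type: ignore[arg-type]
        )
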