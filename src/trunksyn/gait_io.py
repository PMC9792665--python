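"""Gait time-series I/O, cycle segmentation and ensemble statistics.

The universal in-memory currency is :class:`TimeSeriesTable`, a thin labelled
wrapper around a ``(nPt, nCh)`` NumPy array with a strictly increasing time
vector.  Tables read from and write to the OpenSim storage dialect (``.sto`` /
``.mot``: ``key=value`` header lines terminated by ``endheader``, then a
whitespace-delimited numeric body whose first column is ``time``) and to plain
CSV with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal


class FormatError(ValueError):
    """A file does not conform to the expected storage dialect."""


@dataclass
class TimeSeriesTable:
    """Labelled multi-channel time series.

    Parameters
    ----------
    time : ndarray, shape (nPt,)
        Strictly increasing sample times in seconds.
    data : ndarray, shape (nPt, nCh)
        One column per channel.
    labels : list of str
        Channel names, unique, aligned to ``data`` columns (``time`` is not a
        channel).
    metadata : dict
        Free-form string metadata (e.g. ``inDegrees``).
    """

    time: np.ndarray
    data: np.ndarray
    labels: list[str]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != self.time.size:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but time has "
                f"{self.time.size} samples"
            )
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label required per data column")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.data[:, self.labels.index(label)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.labels)
        df.insert(0, "time", self.time)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       metadata: dict[str, str] | None = None
                       ) -> "TimeSeriesTable":
        if "time" not in df.columns:
            raise ValueError("dataframe must contain a 'time' column")
        labels = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(float), df[labels].to_numpy(float),
                   labels, dict(metadata or {}))


@dataclass
class GaitCycleEnsemble:
    """A set of gait cycles resampled to a common 0-100% grid."""

    cycles: list[TimeSeriesTable]
    n_pt: int

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("ensemble needs at least one cycle")
        labels = self.cycles[0].labels
        for i, c in enumerate(self.cycles):
            if c.labels != labels:
                raise ValueError(f"cycle {i} labels differ from cycle 0")
            if c.n_samples != self.n_pt:
                raise ValueError(
                    f"cycle {i} has {c.n_samples} samples, expected {self.n_pt}"
                )


# --------------------------------------------------------------------------
# storage / CSV round-trip
# --------------------------------------------------------------------------

def read_storage(path) -> TimeSeriesTable:
    """Read an OpenSim storage (``.sto``/``.mot``) file.

    Header ``key=value`` lines are kept as metadata; the body must be a
    rectangular whitespace- or tab-delimited numeric block whose first column
    is ``time``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_end = None
    metadata: dict[str, str] = {}
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            header_end = i
            break
        if "=" in line:
            key, _, val = line.partition("=")
            metadata[key.strip()] = val.strip()
        elif line.strip() and i == 0:
            metadata.setdefault("name", line.strip())
    if header_end is None:
        raise FormatError(f"{path}: no 'endheader' line found")
    body = [(n, ln) for n, ln in enumerate(lines[header_end + 1:],
                                           start=header_end + 2)
            if ln.strip()]
    if not body:
        raise FormatError(f"{path}: empty body after endheader")
    columns = body[0][1].split()
    if columns[0] != "time":
        raise FormatError(
            f"{path}:{body[0][0]}: first column must be 'time', got "
            f"{columns[0]!r}"
        )
    rows = []
    for lineno, ln in body[1:]:
        parts = ln.split()
        if len(parts) != len(columns):
            raise FormatError(
                f"{path}:{lineno}: expected {len(columns)} fields, got "
                f"{len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    arr = np.asarray(rows, dtype=float)
    return TimeSeriesTable(arr[:, 0], arr[:, 1:], columns[1:], metadata)


def write_storage(table: TimeSeriesTable, path) -> str:
    """Write ``table`` in OpenSim storage format; lossless to 1e-12."""
    if table.n_channels == 0:
        raise ValueError("cannot write a table with no data channels")
    name = table.metadata.get("name", "trunksyn")
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write(f"version=1\n")
        fh.write(f"nRows={table.n_samples}\n")
        fh.write(f"nColumns={table.n_channels + 1}\n")
        fh.write(f"inDegrees={table.metadata.get('inDegrees', 'no')}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(table.labels) + "\n")
        for t, row in zip(table.time, table.data):
            fh.write("\t".join(f"{v:.15g}" for v in (t, *row)) + "\n")
    return str(path)


def read_csv(path) -> TimeSeriesTable:
    return TimeSeriesTable.from_dataframe(pd.read_csv(path))


def write_csv(table: TimeSeriesTable, path) -> str:
    if table.n_channels == 0:
        raise ValueError("cannot write a table with no data channels")
    table.to_dataframe().to_csv(path, index=False)
    return str(path)


# --------------------------------------------------------------------------
# segmentation / resampling / ensembles
# --------------------------------------------------------------------------

def segment_gait_cycles(table: TimeSeriesTable,
                        right_footstrike_times) -> list[TimeSeriesTable]:
    """Split a trial into gait cycles bounded by consecutive foot strikes.

    Each cycle contains the samples in the half-open window
    ``[t_i, t_{i+1})`` so no sample belongs to two cycles.
    """
    strikes = np.asarray(right_footstrike_times, dtype=float).ravel()
    if strikes.size < 2:
        raise ValueError("need at least two foot-strike times")
    if not np.all(np.diff(strikes) > 0):
        raise ValueError("foot-strike times must be strictly increasing")
    if strikes[0] < table.time[0] or strikes[-1] > table.time[-1]:
        raise ValueError("foot-strike times outside the trial's time range")
    cycles = []
    for t0, t1 in zip(strikes[:-1], strikes[1:]):
        mask = (table.time >= t0) & (table.time < t1)
        if not mask.any():
            raise ValueError(f"no samples in cycle [{t0}, {t1})")
        cycles.append(TimeSeriesTable(table.time[mask], table.data[mask],
                                      list(table.labels),
                                      dict(table.metadata)))
    return cycles


def resample_cycle(cycle: TimeSeriesTable, n_pt: int = 101) -> TimeSeriesTable:
    """Linearly interpolate a cycle onto ``n_pt`` evenly spaced samples."""
    if n_pt < 2:
        raise ValueError("n_pt must be at least 2")
    if cycle.n_samples < 2:
        raise ValueError("cycle needs at least 2 samples to resample")
    new_t = np.linspace(cycle.time[0], cycle.time[-1], n_pt)
    new_d = np.column_stack([
        np.interp(new_t, cycle.time, cycle.data[:, j])
        for j in range(cycle.n_channels)
    ])
    return TimeSeriesTable(new_t, new_d, list(cycle.labels),
                           dict(cycle.metadata))


def ensemble_stats(ensemble: GaitCycleEnsemble
                   ) -> tuple[TimeSeriesTable, TimeSeriesTable]:
    """Per-sample, per-channel mean and sample SD across cycles."""
    stack = np.stack([c.data for c in ensemble.cycles])  # (nCyc, nPt, nCh)
    mean = stack.mean(axis=0)
    sd = (stack.std(axis=0, ddof=1) if stack.shape[0] > 1
          else np.zeros_like(mean))
    grid = np.linspace(0.0, 1.0, ensemble.n_pt)
    labels = list(ensemble.cycles[0].labels)
    return (TimeSeriesTable(grid, mean, labels),
            TimeSeriesTable(grid, sd, list(labels)))


# --------------------------------------------------------------------------
# EMG conditioning
# --------------------------------------------------------------------------

def process_emg(raw: TimeSeriesTable,
                band: tuple[float, float] = (30.0, 300.0),
                envelope_cutoff: float = 6.0,
                normalize: bool = True,
                order: int = 4) -> TimeSeriesTable:
    """Band-pass filter, rectify and low-pass envelope raw EMG.

    Zero-phase Butterworth filters (``filtfilt``); with ``normalize`` each
    channel is scaled by its trial maximum so envelopes peak at 1.  Defaults
    (30-300 Hz band, 6 Hz envelope) are conventional surface-EMG settings and
    fully configurable.
    """
    dt = np.diff(raw.time)
    fs = 1.0 / float(np.mean(dt))
    nyq = fs / 2.0
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= nyq:
        raise ValueError(
            f"band upper edge {hi} Hz is at/above Nyquist ({nyq:.1f} Hz)"
        )
    sos_bp = _signal.butter(order, [lo / nyq, hi / nyq], "bandpass",
                            output="sos")
    rectified = np.abs(_signal.sosfiltfilt(sos_bp, raw.data, axis=0))
    if envelope_cutoff >= nyq:
        raise ValueError("envelope cutoff at/above Nyquist")
    sos_lp = _signal.butter(order, envelope_cutoff / nyq, "low", output="sos")
    env = _signal.sosfiltfilt(sos_lp, rectified, axis=0)
    env = np.clip(env, 0.0, None)
    if normalize:
        peaks = env.max(axis=0)
        nonzero = peaks > 0
        env[:, nonzero] /= peaks[nonzero]
    return TimeSeriesTable(raw.time.copy(), env, list(raw.labels),
                           dict(raw.metadata))
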