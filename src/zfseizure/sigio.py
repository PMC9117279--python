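"""Trace and event-table containers and file formats.

Traces are stored either as two-column delimited text with a commented header
(sampling rate, phase boundaries, subject metadata) or as an HDF5 container
with the same metadata as attributes.  Ground-truth / detected events travel
as a BED-like tab-separated table (recording id, start_s, end_s, kind, ...).
All on-disk times are in seconds, so files are sampling-rate independent.
Intervals are half-open ``[start, end)`` in seconds from recording start.

Proprietary acquisition formats (pClamp/ABF) are not parsed; see
:func:`abf_converter_stub` for the fields a converter would have to supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

EVENT_COLUMNS = ["recording_id", "start", "end", "kind", "peak_amplitude", "n_spikes"]

_REQUIRED_META = ("sampling_rate", "baseline_end", "treatment_end")


class TraceFormatError(ValueError):
    """A trace file is missing required metadata or is malformed."""


@dataclass
class LFPRecording:
    """A local field potential recording with phase boundaries.

    ``samples`` is the voltage trace in mV; ``baseline_end`` and
    ``treatment_end`` delimit the baseline and PTZ-treatment phases in
    seconds from recording start.
    """

    samples: np.ndarray
    sampling_rate: float
    baseline_end: float
    treatment_end: float
    subject: dict = field(default_factory=dict)
    filters_applied: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = len(self.samples) / self.sampling_rate
        if not (0 < self.baseline_end < self.treatment_end <= dur + 1e-9):
            raise ValueError(
                "require 0 < baseline_end < treatment_end <= trace duration "
                f"(got {self.baseline_end}, {self.treatment_end}, {dur:.3f})"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def phase_slice(self, start: float, end: float) -> np.ndarray:
        """Samples of the half-open time window ``[start, end)`` seconds."""
        i0 = int(round(start * self.sampling_rate))
        i1 = int(round(end * self.sampling_rate))
        return self.samples[i0:i1]

    @property
    def baseline(self) -> np.ndarray:
        return self.phase_slice(0.0, self.baseline_end)

    @property
    def treatment(self) -> np.ndarray:
        return self.phase_slice(self.baseline_end, self.treatment_end)


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------


def write_trace(rec: LFPRecording, path, format: str = "text") -> None:
    """Write a recording as delimited text (``text``) or HDF5 (``h5``)."""
    path = Path(path)
    if format == "text":
        header = [
            f"# sampling_rate: {rec.sampling_rate!r}",
            f"# baseline_end: {rec.baseline_end!r}",
            f"# treatment_end: {rec.treatment_end!r}",
        ]
        for key, val in rec.subject.items():
            header.append(f"# subject.{key}: {val}")
        if rec.filters_applied:
            header.append(f"# filters_applied: {rec.filters_applied}")
        header.append("# time_s\tvoltage_mV")
        times = rec.times
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, np.column_stack([times, rec.samples]),
                       fmt="%.9g", delimiter="\t")
    elif format in ("h5", "hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("voltage_mV", data=rec.samples)
            ds.attrs["sampling_rate"] = rec.sampling_rate
            ds.attrs["baseline_end"] = rec.baseline_end
            ds.attrs["treatment_end"] = rec.treatment_end
            ds.attrs["filters_applied"] = rec.filters_applied
            for key, val in rec.subject.items():
                ds.attrs[f"subject.{key}"] = val
    else:
        raise ValueError(f"unknown trace format {format!r}")


def read_trace(path, format: str | None = None) -> LFPRecording:
    """Read a recording; ``format`` is inferred from the suffix if omitted."""
    path = Path(path)
    if format is None:
        format = "h5" if path.suffix in (".h5", ".hdf5") else "text"
    if format == "text":
        meta: dict[str, str] = {}
        subject: dict[str, str] = {}
        with open(path) as fh:
            rows_start = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                rows_start += 1
                body = line[1:].strip()
                if ":" not in body:
                    continue
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key.startswith("subject."):
                    subject[key[len("subject."):]] = val
                else:
                    meta[key] = val
        for req in _REQUIRED_META:
            if req not in meta:
                raise TraceFormatError(
                    f"{path}: missing required header field '{req}'"
                )
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] != 2:
            raise TraceFormatError(f"{path}: expected two columns (time, voltage)")
        return LFPRecording(
            samples=data[:, 1],
            sampling_rate=float(meta["sampling_rate"]),
            baseline_end=float(meta["baseline_end"]),
            treatment_end=float(meta["treatment_end"]),
            subject=subject,
            filters_applied=meta.get("filters_applied", ""),
        )
    if format in ("h5", "hdf5"):
        with h5py.File(path, "r") as fh:
            if "voltage_mV" not in fh:
                raise TraceFormatError(f"{path}: missing 'voltage_mV' dataset")
            ds = fh["voltage_mV"]
            for req in _REQUIRED_META:
                if req not in ds.attrs:
                    raise TraceFormatError(
                        f"{path}: missing required attribute '{req}'"
                    )
            subject = {
                key[len("subject."):]: _from_h5(val)
                for key, val in ds.attrs.items()
                if key.startswith("subject.")
            }
            return LFPRecording(
                samples=ds[()],
                sampling_rate=float(ds.attrs["sampling_rate"]),
                baseline_end=float(ds.attrs["baseline_end"]),
                treatment_end=float(ds.attrs["treatment_end"]),
                subject=subject,
                filters_applied=str(ds.attrs.get("filters_applied", "")),
            )
    raise ValueError(f"unknown trace format {format!r}")


def _from_h5(val):
    return val.decode() if isinstance(val, bytes) else val


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def make_event_table(rows) -> pd.DataFrame:
    """Build a validated event table (sorted, non-overlapping per recording).

    ``rows`` is an iterable of dicts or a DataFrame with at least
    ``recording_id, start, end, kind``.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    for col in ("peak_amplitude", "n_spikes"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[EVENT_COLUMNS].copy()
    if (df["start"] >= df["end"]).any():
        raise ValueError("event table: require start < end for every row")
    df = df.sort_values(["recording_id", "start"], kind="mergesort")
    df = df.reset_index(drop=True)
    for _, grp in df.groupby("recording_id"):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1] - 1e-9).any():
            raise ValueError("event table: overlapping events within a recording")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    """Write a BED-like tab-separated event table (times in s, >=3 decimals)."""
    events = make_event_table(events)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(EVENT_COLUMNS) + "\n")
        for row in events.itertuples(index=False):
            n_spk = "" if pd.isna(row.n_spikes) else str(int(row.n_spikes))
            amp = "" if pd.isna(row.peak_amplitude) else f"{row.peak_amplitude:.6g}"
            fh.write(
                f"{row.recording_id}\t{row.start:.3f}\t{row.end:.3f}\t"
                f"{row.kind}\t{amp}\t{n_spk}\n"
            )


def read_events(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=EVENT_COLUMNS,
            dtype={"recording_id": str, "kind": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    return make_event_table(df)


def abf_converter_stub(path) -> LFPRecording:  # pragma: no cover - documented stub
    """Placeholder for a pClamp/ABF converter.

    A converter must supply: the voltage trace in mV, the sampling rate in Hz,
    and the baseline/treatment phase boundaries in seconds (from the
    experiment log), then construct an :class:`LFPRecording`.
    """
    raise NotImplementedError(
        "ABF parsing is not implemented; export the trace as two-column text "
        "with the required '# sampling_rate/baseline_end/treatment_end' header"
    )
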