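"""Seizure-like / interictal-like event detection and per-recording metrics.

The detector mirrors the study's amplitude/duration rules, normalized to each
fish's own baseline: the rectified deviation from the baseline mean is
envelope-smoothed (moving RMS, 50 ms default); supra-threshold runs at
``ied_amp_factor`` x baseline SD are formed and runs closer than ``merge_gap``
merged; candidates are then classified by duration and raw peak amplitude:

* SLE: duration >= 3 s, peak >= 3 x baseline SD, and >= 5 polyspikes
  (local maxima of the rectified trace above the IED threshold);
* IED: duration in [1, 3) s and peak >= 1.5 x baseline SD;
* anything else is discarded.

Only the treatment phase is scanned; events reaching the window edge are
truncated there.  Classes are half-open: an exactly 3 s event is an SLE
candidate, never an IED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .sigio import LFPRecording, make_event_table


@dataclass(frozen=True)
class DetectionParams:
    sle_amp_factor: float = 3.0      # x baseline SD, raw peak
    ied_amp_factor: float = 1.5      # x baseline SD, envelope threshold + raw peak
    sle_min_duration: float = 3.0    # s
    ied_min_duration: float = 1.0    # s
    ied_max_duration: float = 3.0    # s (== sle_min_duration; IED class is [1, 3))
    min_spikes_sle: int = 5
    merge_gap: float = 0.5           # s
    envelope_smoothing: float = 0.05  # s, moving-RMS window
    spike_min_separation: float = 0.02  # s, between counted polyspike maxima

    def __post_init__(self) -> None:
        if not (self.sle_amp_factor > self.ied_amp_factor > 0):
            raise ValueError("require sle_amp_factor > ied_amp_factor > 0")
        if not (self.ied_min_duration < self.ied_max_duration <= self.sle_min_duration):
            raise ValueError(
                "require ied_min_duration < ied_max_duration <= sle_min_duration"
            )


@dataclass(frozen=True)
class BaselineStats:
    mean: float  # mV
    sd: float    # mV
    window: tuple[float, float]  # (start, end) s


@dataclass
class SeizureMetrics:
    """Per-recording summary. Latency and mean duration are NaN when no SLE."""

    n_sle: int
    sle_per_hour: float
    mean_sle_duration: float  # s
    latency_first_sle: float  # min from treatment onset
    fractional_seizing: float  # % of analysis window
    n_ied: int
    ied_per_hour: float


def estimate_baseline(
    rec: LFPRecording,
    window: tuple[float, float] | None = None,
    min_length: float = 60.0,
) -> BaselineStats:
    """Mean and SD of the (linearly detrended) baseline segment.

    ``window`` defaults to the whole baseline phase; it must lie inside
    ``[0, baseline_end)`` and span at least ``min_length`` seconds.  The SD is
    computed after removing a linear trend, so a DC offset (or slow drift)
    does not inflate it; the reported mean is the raw segment mean.
    """
    if window is None:
        window = (0.0, rec.baseline_end)
    start, end = window
    if not (0.0 <= start < end <= rec.baseline_end + 1e-9):
        raise ValueError("baseline window must lie within the baseline phase")
    if end - start < min_length:
        raise ValueError(f"baseline window must span >= {min_length} s")
    seg = rec.phase_slice(start, end)
    mean = float(seg.mean())
    t = np.arange(len(seg), dtype=float)
    slope, intercept = np.polyfit(t, seg, 1) if len(seg) > 1 else (0.0, mean)
    sd = float((seg - (slope * t + intercept)).std())
    return BaselineStats(mean=mean, sd=sd, window=(start, end))


def moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    """Moving root-mean-square with a centered window of ``n`` samples."""
    return np.sqrt(uniform_filter1d(x * x, size=max(n, 1), mode="nearest"))


def _runs(mask: np.ndarray):
    """Start/end indices (half-open) of True runs."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return np.column_stack([starts, ends])


def detect_events(
    rec: LFPRecording,
    params: DetectionParams | None = None,
    baseline: BaselineStats | None = None,
    recording_id: str | None = None,
) -> pd.DataFrame:
    """Detect SLEs and IEDs in the treatment phase of one recording.

    Returns an event table (columns ``recording_id, start, end, kind,
    peak_amplitude, n_spikes``) with absolute times in seconds from recording
    start.  ``baseline`` must come from the same recording; it defaults to
    :func:`estimate_baseline` over the full baseline phase.
    """
    params = params or DetectionParams()
    baseline = baseline or estimate_baseline(rec)
    if baseline.sd <= 0:
        raise ValueError("baseline SD is zero; detection threshold undefined")
    if recording_id is None:
        recording_id = str(rec.subject.get("id", "rec"))

    fs = rec.sampling_rate
    i0 = int(round(rec.baseline_end * fs))
    i1 = int(round(rec.treatment_end * fs))
    dev = np.abs(rec.samples[i0:i1] - baseline.mean)
    env = moving_rms(dev, int(round(params.envelope_smoothing * fs)))

    thr_env = params.ied_amp_factor * baseline.sd
    runs = _runs(env >= thr_env)
    # merge runs separated by less than merge_gap
    merged = []
    gap = int(round(params.merge_gap * fs))
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_sep = max(int(round(params.spike_min_separation * fs)), 1)
    rows = []
    for s, e in merged:
        dur = (e - s) / fs
        seg = dev[s:e]
        peak = float(seg.max())
        if dur >= params.sle_min_duration:
            pk, _ = find_peaks(seg, height=thr_env, distance=min_sep)
            if peak >= params.sle_amp_factor * baseline.sd and len(pk) >= params.min_spikes_sle:
                rows.append((s, e, "SLE", peak, len(pk)))
        elif params.ied_min_duration <= dur < params.ied_max_duration:
            if peak >= params.ied_amp_factor * baseline.sd:
                rows.append((s, e, "IED", peak, np.nan))
    t_off = rec.baseline_end
    table = [
        {
            "recording_id": recording_id,
            "start": t_off + s / fs,
            "end": min(t_off + e / fs, rec.treatment_end),
            "kind": kind,
            "peak_amplitude": peak,
            "n_spikes": n_spk,
        }
        for s, e, kind, peak, n_spk in rows
    ]
    return make_event_table(table)


def compute_metrics(
    events: pd.DataFrame,
    window_hours: float = 1.0,
    treatment_start: float = 0.0,
) -> SeizureMetrics:
    """Summarize one recording's event table.

    ``treatment_start`` (s) anchors the latency measurement; ``window_hours``
    is the analysis window the rates refer to.  Latency and mean SLE duration
    are NaN (reported missing, not zero) when no SLE occurred.
    """
    sle = events[events["kind"] == "SLE"]
    ied = events[events["kind"] == "IED"]
    n_sle, n_ied = len(sle), len(ied)
    durs = (sle["end"] - sle["start"]).to_numpy()
    window_s = window_hours * 3600.0
    return SeizureMetrics(
        n_sle=n_sle,
        sle_per_hour=n_sle / window_hours,
        mean_sle_duration=float(durs.mean()) if n_sle else float("nan"),
        latency_first_sle=(
            (float(sle["start"].min()) - treatment_start) / 60.0 if n_sle else float("nan")
        ),
        fractional_seizing=100.0 * float(durs.sum()) / window_s,
        n_ied=n_ied,
        ied_per_hour=n_ied / window_hours,
    )


def incidence(metrics_list, predicate=lambda m: m.n_sle >= 1) -> tuple[int, int]:
    """(k, n): number of subjects satisfying ``predicate`` (default >=1 SLE)."""
    k = sum(1 for m in metrics_list if predicate(m))
    return k, len(metrics_list)


def match_events(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    min_overlap: float = 0.5,
    by_kind: bool = True,
):
    """Greedy one-to-one interval matching; returns (tp, fn, fp).

    Two intervals match when their overlap covers at least ``min_overlap`` of
    the shorter interval (and kinds agree when ``by_kind``).
    """
    t = truth.sort_values("start").reset_index(drop=True)
    d = detected.sort_values("start").reset_index(drop=True)
    used = np.zeros(len(d), dtype=bool)
    tp = 0
    for row in t.itertuples(index=False):
        best, best_ov = -1, 0.0
        for j, drow in enumerate(d.itertuples(index=False)):
            if used[j]:
                continue
            if by_kind and drow.kind != row.kind:
                continue
            ov = min(row.end, drow.end) - max(row.start, drow.start)
            shorter = min(row.end - row.start, drow.end - drow.start)
            if ov > 0 and ov / shorter >= min_overlap and ov > best_ov:
                best, best_ov = j, ov
        if best >= 0:
            used[best] = True
            tp += 1
    return tp, len(t) - tp, int((~used).sum())


def event_f1(truth: pd.DataFrame, detected: pd.DataFrame, **kwargs) -> float:
    """Event-level F1 score against ground truth (see :func:`match_events`)."""
    tp, fn, fp = match_events(truth, detected, **kwargs)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
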