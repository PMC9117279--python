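"""Welch power spectral density, spectrograms and delta-band quantification.

Seizure power is quantified as the area under the PSD between 1 and 4 Hz
(delta band), integrated with the trapezoidal rule; the per-recording change
score is AUC(treatment) - AUC(baseline).  Defaults: 4 s Hann windows with 50%
overlap, which resolves the delta band while averaging enough segments over a
10-60 min phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, welch

from .sigio import LFPRecording


@dataclass(frozen=True)
class SpectralParams:
    segment_length: float = 4.0      # s
    overlap: float = 0.5             # fraction of a segment
    window_function: str = "hann"
    delta_band: tuple[float, float] = (1.0, 4.0)  # Hz

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")
        if not (0.0 <= self.delta_band[0] < self.delta_band[1]):
            raise ValueError("delta_band must be an increasing interval")


@dataclass
class PSDResult:
    freqs: np.ndarray   # Hz
    power: np.ndarray   # mV^2 / Hz
    params: SpectralParams


def welch_psd(
    samples: np.ndarray,
    sampling_rate: float,
    params: SpectralParams | None = None,
) -> PSDResult:
    """Welch PSD estimate of one segment (density scaling, mV^2/Hz).

    Parseval-consistent: for white noise the integral of the PSD approximates
    the signal variance.
    """
    params = params or SpectralParams()
    if params.delta_band[1] > sampling_rate / 2:
        raise ValueError("delta_band exceeds the Nyquist frequency")
    nperseg = int(round(params.segment_length * sampling_rate))
    if len(samples) < nperseg:
        raise ValueError(
            f"segment of {len(samples)} samples is shorter than one "
            f"{params.segment_length} s window"
        )
    freqs, power = welch(
        np.asarray(samples, dtype=float),
        fs=sampling_rate,
        window=params.window_function,
        nperseg=nperseg,
        noverlap=int(round(params.overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return PSDResult(freqs=freqs, power=power, params=params)


def band_auc(psd: PSDResult, band: tuple[float, float]) -> float:
    """Trapezoidal area under the PSD over ``band`` (Hz), with the PSD
    linearly interpolated at the band edges."""
    lo, hi = band
    f, p = psd.freqs, psd.power
    inside = (f > lo) & (f < hi)
    grid = np.concatenate([[lo], f[inside], [hi]])
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def delta_auc(psd: PSDResult) -> float:
    """Area under the PSD over the delta band of ``psd.params`` (mV^2)."""
    return band_auc(psd, psd.params.delta_band)


def delta_change_score(
    rec: LFPRecording,
    params: SpectralParams | None = None,
) -> float:
    """Delta-band AUC(treatment) - AUC(baseline) for one recording."""
    params = params or SpectralParams()
    base = welch_psd(rec.baseline, rec.sampling_rate, params)
    treat = welch_psd(rec.treatment, rec.sampling_rate, params)
    return delta_auc(treat) - delta_auc(base)


def group_psd(psds: list[PSDResult]):
    """Mean PSD across recordings with the s.e.m. band.

    All inputs must share one frequency grid.  Returns ``(freqs, mean, sem)``.
    """
    if not psds:
        raise ValueError("no PSDs given")
    f0 = psds[0].freqs
    for p in psds[1:]:
        if len(p.freqs) != len(f0) or not np.allclose(p.freqs, f0):
            raise ValueError("PSDs have differing frequency grids")
    mat = np.vstack([p.power for p in psds])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(len(psds)) if len(psds) > 1 else np.zeros_like(mean)
    return f0, mean, sem


def spectrogram(
    rec_or_samples,
    sampling_rate: float | None = None,
    params: SpectralParams | None = None,
):
    """Short-time power matrix (frequency x time), values >= 0.

    Non-overlapping tiles of ``segment_length`` seconds, each a windowed
    periodogram (density scaling).  Returns ``(freqs, tile_centers_s, power)``.
    The column mean equals a zero-overlap Welch estimate for stationary input.
    """
    params = params or SpectralParams()
    if isinstance(rec_or_samples, LFPRecording):
        samples = rec_or_samples.samples
        sampling_rate = rec_or_samples.sampling_rate
    else:
        samples = np.asarray(rec_or_samples, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare sample array")
    nseg = int(round(params.segment_length * sampling_rate))
    n_tiles = len(samples) // nseg
    if n_tiles < 1:
        raise ValueError("signal shorter than one spectrogram tile")
    tiles = samples[: n_tiles * nseg].reshape(n_tiles, nseg)
    tiles = tiles - tiles.mean(axis=1, keepdims=True)
    win = get_window(params.window_function, nseg)
    spec = np.fft.rfft(tiles * win, axis=1)
    scale = 1.0 / (sampling_rate * (win ** 2).sum())
    power = (np.abs(spec) ** 2) * scale
    power[:, 1:-1] *= 2.0  # one-sided density
    freqs = np.fft.rfftfreq(nseg, d=1.0 / sampling_rate)
    centers = (np.arange(n_tiles) + 0.5) * params.segment_length
    return freqs, centers, power.T
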