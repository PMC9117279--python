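"""Synthetic LFP, behavior, survival and assay generators with known ground truth.

The LFP generator emulates a 10 min baseline + 60 min PTZ-treatment recording:
Gaussian (optionally pink) noise everywhere, plus Poisson-arriving ictal-like
events in the treatment phase.  A seizure-like event (SLE) is an
envelope-modulated polyspike train (>= 5 spikes, 12 Hz intra-event spike rate)
with an added delta-band (2.5 Hz) sinusoid; an interictal-like discharge (IED)
is a shorter (1-3 s) oscillatory burst at lower amplitude.  Peak amplitudes are
fixed multiples of the injected noise SD, so the detector's
baseline-SD-relative thresholds are analytically checkable.

Event bookkeeping: SLE arrival times are homogeneous Poisson after a
deterministic latency offset; arrivals whose intervals would come closer than
``merge_margin`` are merged (SLE-SLE) or discarded (IED colliding with
anything), so the returned ground truth is non-overlapping with a guaranteed
separation.  ``GroundTruth.n_sle_arrivals`` preserves the pre-merge Poisson
count for rate calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import BehaviorTemplate, GenotypeProfile, SimulationConfig, survival_rate_per_hour
from .sigio import LFPRecording

BEHAVIOR_OUTPUTS = [
    "activity",       # Δpixel activity score
    "total_dur",      # total movement duration, s per bin
    "freeze_count",   # 0 mm/s episodes
    "freeze_dur",
    "mid_count",      # 0-20 mm/s episodes
    "mid_dur",
    "burst_count",    # >20 mm/s episodes
    "burst_dur",
]

#: minimum separation enforced between generated events, s
MERGE_MARGIN = 0.8
#: SLE durations are truncated below at this value so that detector edge
#: losses (~0.2 s per side) cannot push a true SLE under the 3 s class limit
SLE_DURATION_FLOOR = 3.3
#: IED true durations, uniform on this interval (detected durations stay in [1, 3))
IED_DURATION_RANGE = (1.3, 2.7)

SPIKE_RATE_HZ = 12.0      # intra-event polyspike rate
SPIKE_WIDTH_S = 0.010     # Gaussian spike half-width
DELTA_FREQ_HZ = 2.5       # oscillatory component injected with each SLE
IED_CARRIER_HZ = 8.0


class CapacityError(ValueError):
    """Requested event rates cannot fit into the treatment window."""


@dataclass
class GroundTruth:
    """Injected events and the generator parameters that produced them."""

    events: pd.DataFrame  # columns: start, end, kind ('SLE'|'IED')
    n_sle_arrivals: int
    seizer: bool
    profile_name: str

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind]


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------


def sample_sle_intervals(
    profile: GenotypeProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    rate_per_hour: float | None = None,
):
    """Sample SLE intervals for one recording.

    Returns ``(intervals, n_arrivals)`` where ``intervals`` is a list of
    merged, non-overlapping ``(start, end)`` pairs in seconds from recording
    start and ``n_arrivals`` the raw Poisson arrival count.  Arrivals are
    homogeneous Poisson on ``[t0 + latency, t_end - mean_duration]`` (the
    "effective window"), so every event fits inside the treatment phase.
    """
    rate = profile.sle_rate if rate_per_hour is None else rate_per_hour
    t0 = config.baseline_duration
    t_end = config.total_duration
    w_lo = t0 + profile.sle_latency * 60.0
    w_hi = t_end - profile.sle_duration_mean
    if rate <= 0 or w_hi <= w_lo:
        return [], 0
    window = w_hi - w_lo
    expected = rate * window / 3600.0
    occupancy = expected * profile.sle_duration_mean / window
    if occupancy > 0.6:
        raise CapacityError(
            f"SLE rate {rate}/h with mean duration {profile.sle_duration_mean}s "
            "would occupy >60% of the treatment window"
        )
    n = rng.poisson(expected)
    starts = np.sort(rng.uniform(w_lo, w_hi, size=n))
    durs = profile.sle_duration_mean + profile.sle_duration_sd * rng.standard_normal(n)
    durs = np.clip(durs, SLE_DURATION_FLOOR, None)
    ends = np.minimum(starts + durs, t_end)
    # merge intervals closer than MERGE_MARGIN
    merged: list[list[float]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < MERGE_MARGIN:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged], int(n)


def sample_ied_intervals(
    profile: GenotypeProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    blocked,
):
    """Sample IED intervals, discarding arrivals that collide with ``blocked``
    intervals (SLEs) or previously accepted IEDs (margin ``MERGE_MARGIN``)."""
    t0 = config.baseline_duration
    t_end = config.total_duration
    w_lo, w_hi = t0, t_end - IED_DURATION_RANGE[1]
    if profile.ied_rate <= 0 or w_hi <= w_lo:
        return []
    expected = profile.ied_rate * (w_hi - w_lo) / 3600.0
    if expected * np.mean(IED_DURATION_RANGE) > 0.6 * (w_hi - w_lo):
        raise CapacityError("IED rate too high for the treatment window")
    n = rng.poisson(expected)
    starts = np.sort(rng.uniform(w_lo, w_hi, size=n))
    durs = rng.uniform(*IED_DURATION_RANGE, size=n)
    kept: list[tuple[float, float]] = []
    occupied = [list(iv) for iv in blocked]
    occupied.sort()
    for s, e in zip(starts, starts + durs):
        collision = any(
            s < oe + MERGE_MARGIN and os_ < e + MERGE_MARGIN
            for os_, oe in occupied
        )
        if not collision:
            kept.append((s, e))
            occupied.append([s, e])
    return kept


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def _tukey(n: int, alpha: float) -> np.ndarray:
    from scipy.signal import windows

    return windows.tukey(n, alpha)


def _sle_waveform(duration: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-peak SLE waveform: polyspike train + delta sinusoid, Tukey envelope."""
    n = max(int(round(duration * fs)), 8)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    delta = 0.55 * np.sin(2 * np.pi * DELTA_FREQ_HZ * t + phase)
    # periodic Gaussian spikes with alternating polarity bias
    cyc = t * SPIKE_RATE_HZ
    frac = cyc - np.floor(cyc)
    sign = np.where(np.floor(cyc) % 3 == 2, -1.0, 1.0)  # mostly-positive polyspikes
    spikes = sign * np.exp(-0.5 * ((frac - 0.5) / (SPIKE_WIDTH_S * SPIKE_RATE_HZ)) ** 2)
    wave = _tukey(n, 0.1) * (delta + spikes)
    return wave / np.max(np.abs(wave))


def _ied_waveform(duration: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-peak IED waveform: short 8 Hz oscillatory burst."""
    n = max(int(round(duration * fs)), 8)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    wave = _tukey(n, 0.2) * np.sin(2 * np.pi * IED_CARRIER_HZ * t + phase)
    return wave / np.max(np.abs(wave))


def _noise(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    white = rng.standard_normal(n)
    if config.noise_model == "white":
        return config.noise_sd * white
    # pink: shape the spectrum by 1/sqrt(f), renormalized to noise_sd
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return config.noise_sd * pink / pink.std()


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_lfp(
    profile: GenotypeProfile,
    config: SimulationConfig,
    seizer: bool | None = None,
    subject_id: str = "sim-0",
) -> tuple[LFPRecording, GroundTruth]:
    """Generate one LFP recording plus its ground truth.

    ``seizer`` controls whether this larva carries SLEs at all; by default it
    is drawn Bernoulli(``profile.incidence``).  Seizing larvae receive rate
    ``sle_rate / incidence`` so the cohort-mean rate matches the profile.
    Identical ``config.seed`` (and arguments) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    if seizer is None:
        seizer = bool(rng.random() < profile.incidence) if profile.incidence > 0 else False
    per_larva_rate = 0.0
    if seizer and profile.incidence > 0:
        per_larva_rate = profile.sle_rate / profile.incidence

    sles, n_arrivals = sample_sle_intervals(profile, config, rng, per_larva_rate)
    ieds = sample_ied_intervals(profile, config, rng, sles)

    trace = _noise(config, rng)
    fs = config.sampling_rate
    rows = []
    for s, e in sles:
        wave = _sle_waveform(e - s, fs, rng)
        i0 = int(round(s * fs))
        amp = profile.sle_amp_factor_true * config.noise_sd
        trace[i0:i0 + len(wave)] += amp * wave
        rows.append({"start": s, "end": e, "kind": "SLE", "peak_amplitude": amp})
    for s, e in ieds:
        wave = _ied_waveform(e - s, fs, rng)
        i0 = int(round(s * fs))
        amp = profile.ied_amp_factor_true * config.noise_sd
        trace[i0:i0 + len(wave)] += amp * wave
        rows.append({"start": s, "end": e, "kind": "IED", "peak_amplitude": amp})
    events = pd.DataFrame(rows, columns=["start", "end", "kind", "peak_amplitude"])
    events = events.sort_values("start").reset_index(drop=True)

    rec = LFPRecording(
        samples=trace,
        sampling_rate=fs,
        baseline_end=config.baseline_duration,
        treatment_end=config.total_duration,
        subject={"id": subject_id, "genotype": profile.name, "drugs": "PTZ"},
        filters_applied="synthetic",
    )
    gt = GroundTruth(
        events=events, n_sle_arrivals=n_arrivals,
        seizer=seizer, profile_name=profile.name,
    )
    return rec, gt


def generate_cohort(
    profile: GenotypeProfile,
    config: SimulationConfig,
    n: int,
    seed: int,
):
    """Generate ``n`` recordings with per-larva seizer status fixed so the
    realized incidence equals ``round(n * profile.incidence)`` exactly."""
    rng = np.random.default_rng(seed)
    n_seizers = int(round(n * profile.incidence))
    status = np.zeros(n, dtype=bool)
    status[rng.choice(n, size=n_seizers, replace=False)] = True
    out = []
    for i in range(n):
        cfg_i = SimulationConfig(
            sampling_rate=config.sampling_rate,
            baseline_duration=config.baseline_duration,
            treatment_duration=config.treatment_duration,
            noise_sd=config.noise_sd,
            noise_model=config.noise_model,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_lfp(profile, cfg_i, seizer=bool(status[i]),
                                subject_id=f"{profile.name}-{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def _derive_outputs(activity: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Map a per-bin Δpixel activity series to the 8 tracker outputs.

    Monotone, saturating transforms of activity plus count noise; durations
    within a 1 min bin sum to <= 60 s.
    """
    a = np.clip(activity, 0.0, None)
    move_frac = a / (a + 80.0)
    total_dur = 60.0 * move_frac
    burst_drive = np.clip(a - 60.0, 0.0, None)
    burst_count = rng.poisson(burst_drive / 12.0)
    burst_dur = np.minimum(burst_count * rng.uniform(0.3, 0.8, size=a.shape), total_dur)
    freeze_dur = 60.0 - total_dur
    freeze_count = rng.poisson(np.clip(freeze_dur / 12.0, 0.0, None))
    mid_dur = np.clip(total_dur - burst_dur, 0.0, None)
    mid_count = rng.poisson(mid_dur / 6.0)
    return {
        "activity": a,
        "total_dur": total_dur,
        "freeze_count": freeze_count.astype(float),
        "freeze_dur": freeze_dur,
        "mid_count": mid_count.astype(float),
        "mid_dur": mid_dur,
        "burst_count": burst_count.astype(float),
        "burst_dur": burst_dur,
    }


def generate_behavior(
    profiles: list[GenotypeProfile],
    n_per_group: int,
    seed: int,
    n_baseline_bins: int = 30,
    n_treatment_bins: int = 60,
    noise_sd: float = 12.0,
) -> pd.DataFrame:
    """Generate a long-format behavior matrix.

    One row per (larva, output, bin): columns ``larva, group, output, phase,
    bin, value``; ``bin`` counts 1 min bins within phase (treatment bin b
    covers minutes (b, b+1] post PTZ).  Group mean activity follows the
    profile's :class:`~zfseizure.profiles.BehaviorTemplate` with additive
    Gaussian noise (``noise_sd`` Δpixel units; 0 reproduces the template
    exactly).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for profile in profiles:
        tmpl = profile.behavior
        t_base = np.full(n_baseline_bins, tmpl.baseline_level)
        t_treat = tmpl.mean_activity(np.arange(1, n_treatment_bins + 1, dtype=float))
        for larva in range(n_per_group):
            name = f"{profile.name}-{larva:03d}"
            for phase, template in (("baseline", t_base), ("treatment", t_treat)):
                act = template + noise_sd * rng.standard_normal(template.shape)
                outputs = _derive_outputs(act, rng)
                for out_name, vals in outputs.items():
                    frames.append(pd.DataFrame({
                        "larva": name,
                        "group": profile.name,
                        "output": out_name,
                        "phase": phase,
                        "bin": np.arange(len(vals)),
                        "value": vals,
                    }))
    return pd.concat(frames, ignore_index=True)


def generate_stage_counts(
    profiles: list[GenotypeProfile],
    n_per_group: int,
    seed: int,
    n_bins: int = 30,
    bin_min: float = 2.0,
) -> pd.DataFrame:
    """Per-larva stage II / III counts per 2 min bin over 1 h of treatment.

    Counts are Poisson draws around a Gaussian-bump group intensity centered
    at the profile's stage-specific peak latency.
    """
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_bins) + 0.5) * bin_min
    rows = []
    for profile in profiles:
        tmpl = profile.behavior
        for stage, peak, width, total in (
            (2, tmpl.stage2_peak_min, tmpl.stage2_width_min, tmpl.stage2_total),
            (3, tmpl.stage3_peak_min, tmpl.stage3_width_min, tmpl.stage3_total),
        ):
            shape = np.exp(-0.5 * ((centers - peak) / width) ** 2)
            lam = total * shape / shape.sum()
            for larva in range(n_per_group):
                counts = rng.poisson(lam)
                rows.append(pd.DataFrame({
                    "larva": f"{profile.name}-{larva:03d}",
                    "group": profile.name,
                    "bin_start_min": centers - bin_min / 2,
                    "stage": stage,
                    "count": counts,
                }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# survival and assays
# ---------------------------------------------------------------------------


def generate_survival(
    profile: GenotypeProfile,
    n: int,
    seed: int,
    horizon: float = 24.0,
) -> pd.DataFrame:
    """Exponential survival times calibrated so E[S(24 h)] = ``survival_24h``.

    Returns a DataFrame with ``time`` (h) and ``event`` (1 = death observed,
    0 = censored at ``horizon``).
    """
    rng = np.random.default_rng(seed)
    lam = survival_rate_per_hour(profile)
    if lam == 0.0:
        times = np.full(n, horizon)
        events = np.zeros(n, dtype=int)
    else:
        raw = rng.exponential(1.0 / lam, size=n) if np.isfinite(lam) else np.zeros(n)
        events = (raw <= horizon).astype(int)
        times = np.minimum(raw, horizon)
    return pd.DataFrame({"time": times, "event": events, "group": profile.name})


def generate_atp_batch(
    true_conc: dict[str, float],
    protein: dict[str, float],
    seed: int,
    slope: float = 2.0e5,
    intercept: float = 500.0,
    rlu_noise: float = 0.01,
    n_replicates: int = 6,
    standards=(0.0, 0.0625, 0.125, 0.25, 0.5, 1.0),
):
    """Synthetic luminescence plate: linear RLU response to [ATP] (µM).

    Returns ``(standard_df, sample_df)`` where the standard curve has columns
    ``conc, rlu`` and samples have ``sample, rlu, protein`` (replicates as
    rows).  Multiplicative RLU noise with fraction ``rlu_noise``.
    """
    rng = np.random.default_rng(seed)
    std_rows = [
        {"conc": c, "rlu": (intercept + slope * c) * (1 + rlu_noise * rng.standard_normal())}
        for c in standards for _ in range(2)
    ]
    samp_rows = []
    for name, conc in true_conc.items():
        for _ in range(n_replicates):
            rlu = (intercept + slope * conc) * (1 + rlu_noise * rng.standard_normal())
            samp_rows.append({"sample": name, "rlu": rlu, "protein": protein[name]})
    return pd.DataFrame(std_rows), pd.DataFrame(samp_rows)


def generate_qpcr_batch(
    fold_changes: dict[str, float],
    seed: int,
    reference_gene: str = "ref",
    n_replicates: int = 3,
    base_ct: float = 22.0,
    ct_noise: float = 0.15,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Synthetic Ct table for control vs treated groups.

    ``fold_changes`` maps target gene -> true expression ratio (treated over
    control); treated Ct is shifted by -log_E(fold).  Returns long format with
    columns ``gene, group, ct`` plus the reference gene at fold 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    genes = dict(fold_changes)
    genes.setdefault(reference_gene, 1.0)
    for gene, fold in genes.items():
        shift = -np.log(fold) / np.log(efficiency)
        for group, delta in (("control", 0.0), ("treated", shift)):
            for _ in range(n_replicates):
                rows.append({
                    "gene": gene,
                    "group": group,
                    "ct": base_ct + delta + ct_noise * rng.standard_normal(),
                })
    return pd.DataFrame(rows)
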