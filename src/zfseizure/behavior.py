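"""Locomotor activity curves, AUC analytics and stage II/III aggregation.

Behavior matrices are long-format DataFrames (columns ``larva, group, output,
phase, bin, value``) as produced by :func:`zfseizure.synth.generate_behavior`;
stage-count tables have columns ``larva, group, bin_start_min, stage, count``.
Stage I is not quantified (it has no unambiguous scoring criterion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default baseline window used for baseline subtraction: the final 15 min of
#: the 30 min baseline phase, where activity has stabilized
BASELINE_SUBTRACTION_WINDOW_MIN = 15.0


def activity_curve(
    matrix: pd.DataFrame,
    output: str = "activity",
    phase: str = "treatment",
) -> pd.DataFrame:
    """Group mean +/- s.e.m. per time bin for one output.

    Returns a DataFrame indexed by (group, bin) with columns ``mean, sem, n``;
    ``sem`` is NaN for a single larva.
    """
    sel = matrix[(matrix["output"] == output) & (matrix["phase"] == phase)]
    g = sel.groupby(["group", "bin"])["value"]
    out = g.agg(mean="mean", sem="sem", n="count")
    return out


def larva_auc(
    matrix: pd.DataFrame,
    output: str = "activity",
    phase: str = "treatment",
    interval: tuple[float, float] | None = None,
    subtract_baseline: bool = False,
    bin_min: float = 1.0,
) -> pd.DataFrame:
    """Per-larva trapezoidal AUC (Δpixel·min) of one output.

    Bin ``b`` is centered at ``(b + 0.5) * bin_min`` minutes within its phase.
    With ``subtract_baseline`` the larva's mean activity over the final
    15 min of its baseline phase is subtracted from the curve before
    integrating, so a pure-baseline period integrates to ~0.
    """
    sel = matrix[(matrix["output"] == output) & (matrix["phase"] == phase)]
    base_means = {}
    if subtract_baseline:
        base = matrix[(matrix["output"] == output) & (matrix["phase"] == "baseline")]
        n_base_bins = base["bin"].max() + 1 if len(base) else 0
        cutoff = n_base_bins - BASELINE_SUBTRACTION_WINDOW_MIN / bin_min
        tail = base[base["bin"] >= cutoff]
        base_means = tail.groupby("larva")["value"].mean().to_dict()
    rows = []
    for (larva, group), grp in sel.groupby(["larva", "group"]):
        grp = grp.sort_values("bin")
        t = (grp["bin"].to_numpy() + 0.5) * bin_min
        v = grp["value"].to_numpy(dtype=float)
        if subtract_baseline:
            v = v - base_means.get(larva, 0.0)
        if interval is not None:
            m = (t >= interval[0]) & (t <= interval[1])
            t, v = t[m], v[m]
        rows.append({"larva": larva, "group": group,
                     "auc": curve_auc(t, v)})
    return pd.DataFrame(rows)


def curve_auc(
    t_min: np.ndarray,
    values: np.ndarray,
    interval: tuple[float, float] | None = None,
    baseline_mean: float | None = None,
) -> float:
    """Trapezoidal AUC of a sampled curve (units: value·min).

    If ``baseline_mean`` is given it is subtracted before integrating.
    """
    t = np.asarray(t_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if baseline_mean is not None:
        v = v - baseline_mean
    if interval is not None:
        lo, hi = interval
        grid = np.concatenate([[lo], t[(t > lo) & (t < hi)], [hi]])
        v = np.interp(grid, t, v)
        t = grid
    return float(np.trapezoid(v, t))


def stage_summary(stages: pd.DataFrame, majority_fraction: float = 0.5) -> pd.DataFrame:
    """Aggregate stage-count tables per (group, stage).

    Returns one row per (group, stage) with:

    * ``total``: mean per-larva total count over the hour;
    * ``peak_latency_min``: center of the bin with the highest group-mean
      count (earliest bin on ties; NaN when all counts are zero);
    * ``onset_bin_min``: start of the first bin where the group-mean count is
      positive (NaN if none);
    * ``n_majority_bins``: number of bins in which at least
      ``majority_fraction`` of larvae have a count >= 1.
    """
    rows = []
    bin_width = _bin_width(stages)
    for (group, stage), grp in stages.groupby(["group", "stage"]):
        per_bin = grp.groupby("bin_start_min")["count"]
        mean_counts = per_bin.mean()
        n_larvae = grp["larva"].nunique()
        active_frac = grp[grp["count"] >= 1].groupby("bin_start_min")["larva"].nunique() / n_larvae
        active_frac = active_frac.reindex(mean_counts.index, fill_value=0.0)
        if mean_counts.max() > 0:
            peak_bin = mean_counts.index[np.argmax(mean_counts.to_numpy())]
            peak_latency = peak_bin + bin_width / 2.0
            onset = mean_counts.index[np.argmax(mean_counts.to_numpy() > 0)]
        else:
            peak_latency = float("nan")
            onset = float("nan")
        rows.append({
            "group": group,
            "stage": stage,
            "total": float(grp.groupby("larva")["count"].sum().mean()),
            "peak_latency_min": peak_latency,
            "onset_bin_min": onset,
            "n_majority_bins": int((active_frac >= majority_fraction).sum()),
        })
    return pd.DataFrame(rows)


def _bin_width(stages: pd.DataFrame) -> float:
    starts = np.sort(stages["bin_start_min"].unique())
    return float(starts[1] - starts[0]) if len(starts) > 1 else 2.0
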