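#!/usr/bin/env python
"""Simulate per-genotype LFP cohorts and run the event detector.

For each genotype profile: generate a small cohort of 70 min recordings
(10 min baseline + 60 min PTZ) at 1 kHz, detect seizure-like and
interictal-like events against each fish's own baseline, and summarize
per-recording metrics (SLE/h, duration, latency, fractional seizing, IED/h)
plus cohort incidence and detector accuracy against the generator's ground
truth.  Writes results/seizure_metrics.csv and results/cohort_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from zfseizure import detect, synth
from zfseizure.profiles import SimulationConfig, get_profile

N_PER_GROUP = 6  # desk-scale cohort; the study used 7-12 larvae per genotype
SEED = 20_220_518


def main() -> None:
    rng = np.random.default_rng(SEED)
    metric_rows, summary_rows = [], []
    for name in ("TL", "panx1a", "panx1b", "DKO", "PROB"):
        prof = get_profile(name)
        cfg = SimulationConfig(seed=int(rng.integers(2**31)))
        cohort = synth.generate_cohort(prof, cfg, N_PER_GROUP,
                                       seed=int(rng.integers(2**31)))
        metrics, f1s = [], []
        for rec, gt in cohort:
            events = detect.detect_events(rec)
            m = detect.compute_metrics(events, 1.0, rec.baseline_end)
            metrics.append(m)
            if len(gt.events):
                f1s.append(detect.event_f1(gt.events, events))
            metric_rows.append({"genotype": prof.name,
                                "recording_id": rec.subject["id"],
                                **m.__dict__})
        k, n = detect.incidence(metrics)
        summary_rows.append({
            "genotype": prof.name,
            "incidence": f"{k}/{n}",
            "sle_per_hour_mean": np.mean([m.sle_per_hour for m in metrics]),
            "mean_duration_s": np.nanmean(
                [m.mean_sle_duration for m in metrics]) if k else np.nan,
            "latency_min_mean": np.nanmean(
                [m.latency_first_sle for m in metrics]) if k else np.nan,
            "fractional_seizing_pct": np.mean(
                [m.fractional_seizing for m in metrics]),
            "ied_per_hour_mean": np.mean([m.ied_per_hour for m in metrics]),
            "event_f1_vs_ground_truth": np.mean(f1s) if f1s else np.nan,
        })
    out = Path("results")
    out.mkdir(exist_ok=True)
    pd.DataFrame(metric_rows).to_csv(out / "seizure_metrics.csv", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    print(summary.round(2).to_string(index=False))
    print("\nSeizing genotypes (TL, panx1b-/-) show tens of SLEs per hour and "
          "minute-scale latencies; knockout of panx1a nearly abolishes SLEs "
          "while interictal discharges persist at reduced rates.")


if __name__ == "__main__":
    main()
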