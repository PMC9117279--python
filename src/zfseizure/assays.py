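"""ATP quantification and REST-style qPCR relative expression.

ATP: sample luminescence is converted to concentration by inverting a linear
least-squares fit of the 0-1 µM standard curve, normalized to protein content
(mg/ml) and scaled to a reference group (reference maps to 1).

qPCR: the efficiency-corrected expression ratio R = E_t^dCt_t / E_r^dCt_r
(dCt = mean Ct(control) - mean Ct(treated)), with a fixed-reallocation
randomization test: control/treated labels are reallocated jointly across
target and reference replicates, R recomputed, and the two-sided p-value is
the fraction of reallocations with |log R| at least as large as observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# ATP
# ---------------------------------------------------------------------------


def fit_standard_curve(standards: pd.DataFrame):
    """Least-squares RLU = slope * conc + intercept; needs >= 2 points and a
    positive slope (luminescence must increase with [ATP])."""
    conc = standards["conc"].to_numpy(dtype=float)
    rlu = standards["rlu"].to_numpy(dtype=float)
    if len(conc) < 2:
        raise ValueError("standard curve needs at least two points")
    slope, intercept = np.polyfit(conc, rlu, 1)
    if slope <= 0:
        raise ValueError("standard curve has non-positive slope")
    return float(slope), float(intercept)


def atp_quantify(
    standards: pd.DataFrame,
    samples: pd.DataFrame,
    reference_group: str,
) -> pd.DataFrame:
    """Normalized [ATP] per mg protein, scaled to the reference group.

    ``samples`` columns: ``sample`` (group label), ``rlu`` (replicate
    luminescence), ``protein`` (mg/ml).  Per-group replicate RLUs are
    inverted through the standard curve, divided by protein, then divided by
    the reference-group mean so the reference maps to 1.0.
    Returns per-group rows: ``sample, conc_uM, per_mg, normalized``.
    """
    slope, intercept = fit_standard_curve(standards)
    df = samples.copy()
    if (df["protein"] <= 0).any():
        raise ValueError("protein content must be positive")
    df["conc_uM"] = (df["rlu"] - intercept) / slope
    df["per_mg"] = df["conc_uM"] / df["protein"]
    per_group = df.groupby("sample", sort=False).agg(
        conc_uM=("conc_uM", "mean"), per_mg=("per_mg", "mean"),
    ).reset_index()
    if reference_group not in set(per_group["sample"]):
        raise ValueError(f"reference group {reference_group!r} not in samples")
    ref = float(per_group.loc[per_group["sample"] == reference_group, "per_mg"].iloc[0])
    per_group["normalized"] = per_group["per_mg"] / ref
    return per_group


# ---------------------------------------------------------------------------
# qPCR (REST / Pfaffl)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QPCRBatch:
    """Ct replicates per gene and group plus per-gene efficiencies.

    ``data``: long format with columns ``gene, group, ct`` where group is
    'control' or 'treated'.  ``efficiencies`` maps gene -> amplification
    efficiency E in (1, 2]; genes not listed default to 2.0 (perfect
    doubling).
    """

    data: pd.DataFrame
    efficiencies: dict | None = None

    def efficiency(self, gene: str) -> float:
        e = 2.0 if self.efficiencies is None else self.efficiencies.get(gene, 2.0)
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {gene!r} must lie in (1, 2]")
        return e

    def cts(self, gene: str, group: str) -> np.ndarray:
        sel = self.data[(self.data["gene"] == gene) & (self.data["group"] == group)]
        if sel.empty:
            raise ValueError(f"no Ct replicates for gene={gene!r}, group={group!r}")
        vals = sel["ct"].to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("Ct values must be positive")
        return vals


def _ratio(ct_tc, ct_tt, ct_rc, ct_rt, e_t, e_r) -> float:
    d_t = np.mean(ct_tc) - np.mean(ct_tt)
    d_r = np.mean(ct_rc) - np.mean(ct_rt)
    return float(e_t ** d_t / e_r ** d_r)


def rest_ratio(batch: QPCRBatch, target: str, reference_gene: str) -> float:
    """Efficiency-corrected relative expression ratio (treated vs control).

    R = E_target^(dCt_target) / E_ref^(dCt_ref); R = 1 means no change and a
    constant Ct shift applied to every well leaves R unchanged.
    """
    return _ratio(
        batch.cts(target, "control"), batch.cts(target, "treated"),
        batch.cts(reference_gene, "control"), batch.cts(reference_gene, "treated"),
        batch.efficiency(target), batch.efficiency(reference_gene),
    )


def rest_randomization_test(
    batch: QPCRBatch,
    target: str,
    reference_gene: str,
    n_rand: int = 2000,
    seed: int = 0,
    exact: bool | None = None,
) -> float:
    """Pairwise fixed-reallocation randomization test (two-sided on |log R|).

    Replicates keep their (target, reference) pairing; only the
    control/treated labels are reallocated.  ``exact=None`` enumerates all
    C(n, n_control) reallocations when there are at most ``n_rand`` of them,
    otherwise samples ``n_rand`` reallocations with the add-one estimator.
    """
    ct_t = np.concatenate([batch.cts(target, "control"), batch.cts(target, "treated")])
    ct_r = np.concatenate([batch.cts(reference_gene, "control"),
                           batch.cts(reference_gene, "treated")])
    if len(ct_t) != len(ct_r):
        raise ValueError("fixed reallocation requires paired target/reference wells")
    nc = len(batch.cts(target, "control"))
    n = len(ct_t)
    e_t = batch.efficiency(target)
    e_r = batch.efficiency(reference_gene)

    def log_ratio(ctrl_idx: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[ctrl_idx] = True
        return abs(np.log(_ratio(ct_t[mask], ct_t[~mask], ct_r[mask], ct_r[~mask],
                                 e_t, e_r)))

    obs = log_ratio(np.arange(nc))
    if exact is None:
        exact = comb(n, nc) <= n_rand
    if exact:
        hits = total = 0
        for idx in combinations(range(n), nc):
            total += 1
            if log_ratio(np.array(idx)) >= obs - 1e-12:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rand):
        idx = rng.choice(n, size=nc, replace=False)
        if log_ratio(idx) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_rand + 1)
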