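"""Batch self-organizing-map behavioral phenotyping.

A 4x4 hexagonal SOM is trained in batch mode (all samples presented at once,
200 iterations) on standardized per-(larva, minute-bin) feature vectors of the
8 tracker outputs.  The neighborhood is a step function of link distance
(graph distance on the hex lattice) whose radius shrinks from 3 to 1 over
training.  Each larva is assigned the modal best-matching unit (BMU) of its
per-bin samples; genotype similarity is the mean absolute per-node difference
in larvae counts (smaller = more similar).

Weight initialization is deterministic (linear along the first two principal
axes of the data), so training does not depend on the seed; the seed only
drives the Monte-Carlo permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .synth import BEHAVIOR_OUTPUTS


@dataclass(frozen=True)
class SOMParams:
    shape: tuple[int, int] = (4, 4)
    n_iterations: int = 200
    radius_start: float = 3.0
    radius_end: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("grid shape must be positive")


@dataclass
class FeatureSet:
    """Standardized samples plus their (larva, group, bin) metadata."""

    X: np.ndarray            # (n_samples, n_features), z-scored per feature
    meta: pd.DataFrame       # columns larva, group, bin
    outputs: list[str]
    means: np.ndarray
    sds: np.ndarray

    def destandardize(self) -> np.ndarray:
        return self.X * self.sds + self.means


@dataclass
class SOMModel:
    weights: np.ndarray      # (n_nodes, n_features)
    coords: np.ndarray       # (n_nodes, 2) hex positions
    link_dist: np.ndarray    # (n_nodes, n_nodes) integer graph distances
    params: SOMParams
    quantization_errors: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.weights)


def hex_grid(shape: tuple[int, int]):
    """Hexagonal node coordinates (odd rows offset) and link distances."""
    rows, cols = shape
    coords = np.array([
        (c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0)
        for r in range(rows) for c in range(cols)
    ])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    adj = (d > 0) & (d <= 1.01)
    link = shortest_path(adj.astype(float), method="D", unweighted=True)
    return coords, link


def build_features(
    matrix: pd.DataFrame,
    outputs: list[str] | None = None,
    phase: str = "treatment",
) -> FeatureSet:
    """One sample per (larva, treatment bin) with the 8 outputs as features.

    Each output is standardized to zero mean / unit variance across all
    samples; a constant output maps to all-zeros (guarded divide).
    """
    outputs = outputs or list(BEHAVIOR_OUTPUTS)
    sel = matrix[(matrix["phase"] == phase) & (matrix["output"].isin(outputs))]
    wide = sel.pivot_table(
        index=["larva", "group", "bin"], columns="output", values="value",
    )[outputs]
    if wide.isna().any().any():
        raise ValueError("behavior matrix has missing (larva, bin, output) cells")
    X = wide.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    # constant columns (up to floating-point residue) standardize to zeros
    tiny = 1e-9 * np.maximum(1.0, np.abs(means))
    constant = sds <= tiny
    sds_safe = np.where(constant, 1.0, sds)
    Xz = (X - means) / sds_safe
    Xz[:, constant] = 0.0
    meta = wide.index.to_frame(index=False)
    return FeatureSet(X=Xz, meta=meta, outputs=outputs, means=means, sds=sds_safe)


def _linear_init(X: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Deterministic initialization along the first two principal axes."""
    rows, cols = shape
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_pc = min(2, vt.shape[0])
    # fix sign: largest-magnitude loading positive
    for i in range(n_pc):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    sd = s / np.sqrt(max(len(X) - 1, 1))
    u = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.zeros(1)
    v = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.zeros(1)
    W = np.tile(mean, (rows * cols, 1))
    k = 0
    for r in range(rows):
        for c in range(cols):
            W[k] += u[c] * sd[0] * vt[0]
            if n_pc > 1:
                W[k] += v[r] * sd[1] * vt[1]
            k += 1
    return W


def bmu(weights: np.ndarray, X: np.ndarray, feature_mask=None) -> np.ndarray:
    """Index of the best-matching unit for each sample row."""
    W = weights
    if feature_mask is not None:
        mask = np.asarray(feature_mask, dtype=bool)
        W = W[:, mask]
        X = X[:, mask]
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=1)


def quantization_error(weights: np.ndarray, X: np.ndarray) -> float:
    """Mean Euclidean distance of samples to their BMU."""
    d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.min(axis=1)).mean())


def train_som(X: np.ndarray, params: SOMParams | None = None) -> SOMModel:
    """Batch-train a hexagonal SOM.

    Each iteration: compute BMUs, then replace every node's weight by the
    plain mean of all samples whose BMU lies within the current link-distance
    radius of that node (empty neighborhoods keep their weight).  The radius
    shrinks in integer steps from ``radius_start`` to ``radius_end``; each
    radius phase runs an equal share of ``n_iterations``.
    """
    params = params or SOMParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training requires a non-empty 2-D sample array")
    coords, link = hex_grid(params.shape)
    W = _linear_init(X, params.shape)
    n_nodes = len(W)
    radii = np.linspace(params.radius_start, params.radius_end, params.n_iterations)
    qe_cur = quantization_error(W, X)
    qe = [qe_cur]
    for radius in radii:
        b = bmu(W, X)
        H = (link <= radius + 1e-9).astype(float)  # (bmu_node, node)
        counts = np.zeros(n_nodes)
        sums = np.zeros_like(W)
        np.add.at(counts, b, 1.0)
        np.add.at(sums, b, X)
        denom = H.T @ counts
        numer = H.T @ sums
        nz = denom > 0
        target = W.copy()
        target[nz] = numer[nz] / denom[nz, None]
        # backtracking safeguard: the step-neighborhood batch rule can
        # flip-flop between assignment configurations; halve the step until
        # the quantization error does not increase (keep W if even a tiny
        # step ascends).  The full step is accepted in the common case.
        accepted = False
        for alpha in (1.0, 0.5, 0.25, 0.125):
            cand = W + alpha * (target - W)
            qe_cand = quantization_error(cand, X)
            if qe_cand <= qe_cur + 1e-12:
                W, qe_cur, accepted = cand, qe_cand, True
                break
        if not accepted:
            pass  # keep current weights for this iteration
        qe.append(qe_cur)
    model = SOMModel(weights=W, coords=coords, link_dist=link, params=params)
    model.quantization_errors = qe
    return model


def classify_larvae(
    model: SOMModel,
    features: FeatureSet,
    feature_mask=None,
) -> pd.DataFrame:
    """Assign each larva its modal BMU over its per-bin samples.

    Ties are broken by the lowest node index.  ``feature_mask`` restricts the
    BMU distance to a subset of features (per-output classification maps).
    Returns columns ``larva, group, node``.
    """
    nodes = bmu(model.weights, features.X, feature_mask)
    df = features.meta.assign(node=nodes)
    rows = []
    for (larva, group), grp in df.groupby(["larva", "group"], sort=True):
        counts = np.bincount(grp["node"], minlength=model.n_nodes)
        rows.append({"larva": larva, "group": group, "node": int(counts.argmax())})
    return pd.DataFrame(rows)


def project(model: SOMModel, features: FeatureSet, feature_mask=None) -> pd.DataFrame:
    """Classify a new group on an already-trained map (no retraining)."""
    return classify_larvae(model, features, feature_mask)


def node_counts(assignments: pd.DataFrame, group: str, n_nodes: int = 16) -> np.ndarray:
    sel = assignments[assignments["group"] == group]
    return np.bincount(sel["node"].to_numpy(), minlength=n_nodes).astype(float)


def similarity(
    assignments: pd.DataFrame,
    g1: str,
    g2: str,
    n_nodes: int = 16,
) -> float:
    """Mean absolute per-node difference in classified-larvae counts.

    0 for identical distributions; all-36-in-one-node vs all-36-in-another
    scores (36 + 36) / 16 = 4.5.  Symmetric in its group arguments.
    """
    c1 = node_counts(assignments, g1, n_nodes)
    c2 = node_counts(assignments, g2, n_nodes)
    return float(np.abs(c1 - c2).mean())


def similarity_matrix(assignments: pd.DataFrame, n_nodes: int = 16) -> pd.DataFrame:
    groups = sorted(assignments["group"].unique())
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for g1, g2 in combinations(groups, 2):
        s = similarity(assignments, g1, g2, n_nodes)
        mat.loc[g1, g2] = mat.loc[g2, g1] = s
    return mat


def _chi2_statistic(c1: np.ndarray, c2: np.ndarray) -> float:
    n1, n2 = c1.sum(), c2.sum()
    tot = c1 + c2
    stat = 0.0
    for o, e_frac in ((c1, n1), (c2, n2)):
        e = tot * e_frac / (n1 + n2)
        nz = e > 0
        stat += (((o - e) ** 2)[nz] / e[nz]).sum()
    return float(stat)


def cluster_contingency_test(
    assignments: pd.DataFrame,
    g1: str,
    g2: str,
    n_nodes: int = 16,
    n_permutations: int = 100_000,
    seed: int = 0,
    exact: bool | None = None,
) -> float:
    """Exact-style test on the 2 x n_nodes larvae-count table.

    The chi-square statistic orders tables; the p-value is computed either by
    exhaustive enumeration over all label reassignments (``exact=True``,
    feasible for small groups) or by Monte-Carlo permutation with the add-one
    estimator.  ``exact=None`` picks enumeration when C(n1+n2, n1) <= 20000.
    """
    sel = assignments[assignments["group"].isin([g1, g2])]
    nodes = sel["node"].to_numpy()
    labels = (sel["group"] == g1).to_numpy()
    n1 = int(labels.sum())
    n = len(labels)

    def stat_for(mask: np.ndarray) -> float:
        c1 = np.bincount(nodes[mask], minlength=n_nodes).astype(float)
        c2 = np.bincount(nodes[~mask], minlength=n_nodes).astype(float)
        return _chi2_statistic(c1, c2)

    obs = stat_for(labels)
    from math import comb

    if exact is None:
        exact = comb(n, n1) <= 20_000
    if exact:
        n_ge = 0
        total = 0
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            total += 1
            if stat_for(mask) >= obs - 1e-12:
                n_ge += 1
        return n_ge / total
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n1]] = True
        if stat_for(mask) >= obs - 1e-12:
            n_ge += 1
    return (n_ge + 1) / (n_permutations + 1)
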