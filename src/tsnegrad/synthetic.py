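"""Synthetic cluster data with known ground-truth feature dependencies.

Each sample starts as isotropic Gaussian noise in R^d; a cluster is created
by translating a small, disjoint subset of features by a fixed shift.  One
cluster (label 0) receives no translation at all, so the generator knows
exactly which features carry cluster identity — the "truth" an attribution
method should recover.  With ``hierarchy=True`` consecutive signal clusters
share one truth feature, inducing super-cluster structure.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import mannwhitneyu

from ._errors import ParameterError
from .attribution import AttributionMatrix, aggregate_by_group
from .io import DataMatrix


@dataclasses.dataclass
class SyntheticSpec:
    """Generator parameters; cluster 0 is always the null (untranslated) cluster."""

    n_per_cluster: int = 75
    n_clusters: int = 4
    d: int = 30
    features_per_cluster: int = 5
    shift: float = 6.0
    noise_sd: float = 1.0
    seed: int = 0
    hierarchy: bool = False

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ParameterError("need at least 2 clusters (one null, one signal)")
        if self.features_per_cluster * (self.n_clusters - 1) > self.d:
            raise ParameterError(
                "features_per_cluster * (n_clusters - 1) must not exceed d"
            )
        if self.shift < 0 or self.noise_sd <= 0:
            raise ParameterError("shift must be >= 0 and noise_sd > 0")


@dataclasses.dataclass
class SyntheticDataset:
    X: DataMatrix
    labels: np.ndarray
    truth: dict  # cluster id -> set of feature indices (empty for the null cluster)
    spec: SyntheticSpec

    @property
    def truth_union(self) -> set:
        out: set = set()
        for s in self.truth.values():
            out |= s
        return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the dataset; bit-reproducible from the spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_cluster * spec.n_clusters
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
    labels = np.repeat(np.arange(spec.n_clusters), spec.n_per_cluster)
    truth: dict = {0: set()}
    nxt = 0
    for c in range(1, spec.n_clusters):
        feats = list(range(nxt, nxt + spec.features_per_cluster))
        nxt += spec.features_per_cluster
        truth[c] = set(feats)
    if spec.hierarchy and spec.n_clusters >= 4:
        # pair signal clusters (1,2), (3,4), ...; the second of each pair
        # swaps its last feature for the first feature of its partner
        signal = list(range(1, spec.n_clusters))
        for a, b in zip(signal[0::2], signal[1::2]):
            feats_b = sorted(truth[b])
            feats_b[-1] = min(truth[a])
            truth[b] = set(feats_b)
    for c in range(1, spec.n_clusters):
        rows = labels == c
        for f in truth[c]:
            X[rows, f] += spec.shift
    dm = DataMatrix.from_values(
        X,
        feature_names=[f"f{j}" for j in range(spec.d)],
        sample_ids=[f"s{i}" for i in range(n)],
    )
    return SyntheticDataset(X=dm, labels=labels, truth=truth, spec=spec)


@dataclasses.dataclass
class RecoverySummary:
    """Per-cluster separation of truth vs non-truth feature scores."""

    per_cluster: dict  # cluster -> {"auroc": float|None, "p_value": float, "top_decile_fraction": float}
    scores: np.ndarray  # group x d aggregated |mean attribution|
    groups: list


def _auroc(scores: np.ndarray, positives: set) -> float | None:
    labels = np.array([1 if j in positives else 0 for j in range(scores.size)])
    if labels.sum() == 0 or labels.sum() == labels.size:
        return None
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def score_recovery(A: AttributionMatrix | np.ndarray, data: SyntheticDataset) -> RecoverySummary:
    """Test whether class-averaged |attributions| rank truth features first.

    For each signal cluster: AUROC of the aggregated score as a classifier of
    truth membership, a one-sided rank-sum p-value (truth > rest), and the
    fraction of truth features landing in the score's top decile.  The null
    cluster has no truth features of its own; it is scored against the union
    of every cluster's truth features, since the null cluster's placement is
    still driven by the features that define its neighbors.
    """
    groups, agg = aggregate_by_group(A, data.labels)
    per_cluster = {}
    d = agg.shape[1]
    decile = max(1, int(round(d / 10.0)))
    for gi, g in enumerate(groups):
        positives = data.truth.get(g, set())
        if not positives:
            positives = data.truth_union
        scores = agg[gi]
        auroc = _auroc(scores, positives)
        pos = sorted(positives)
        neg = [j for j in range(d) if j not in positives]
        if pos and neg:
            p = float(mannwhitneyu(scores[pos], scores[neg], alternative="greater").pvalue)
        else:
            p = float("nan")
        top = set(np.argsort(-scores, kind="stable")[:decile].tolist())
        frac = len(top & set(pos)) / len(pos) if pos else float("nan")
        per_cluster[g] = {"auroc": auroc, "p_value": p, "top_decile_fraction": frac}
    return RecoverySummary(per_cluster=per_cluster, scores=agg, groups=groups)
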