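"""Corruption-based validation of feature attributions.

The logic of the experiment: if an attribution method really finds the
features a t-SNE embedding relies on, then corrupting the top-ranked
features and re-embedding should degrade the embedding more than corrupting
random features.  Degradation is measured between the reference embedding
and the post-corruption embedding with three complementary metrics:

* Spearman correlation of all pairwise embedded distances (global structure),
* adjusted Rand index between K-means clusterings (cluster structure),
* mean fraction of each point's 10 nearest neighbors retained (local
  structure).

Selection can be per-sample (local), per-class, or dataset-wide (global);
corruption can replace selected cells by their mean, permute them within a
feature, or (globally) remove the feature columns.  Baselines cover random
subsets, |feature| enrichment, Laplacian and Fisher scores, and a
PCA-variance control.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from ._errors import ParameterError
from .affinity import calibrate_affinities
from .attribution import fit_attributions
from .io import DataMatrix
from .tsne import OptimizerConfig, fit, student_t_kernel

LEVELS = ("local", "class", "global")
METHODS = ("mean", "permute", "remove")
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.02, 0.181, 0.02), 2))


# ---------------------------------------------------------------------------
# feature selection and corruption


@dataclasses.dataclass
class CorruptionPlan:
    """Which cells to corrupt, and how."""

    level: str  # local | class | global
    method: str  # mean | permute | remove
    fraction: float
    selected: object  # local: (n, k) int array; class: {label: sorted list}; global: sorted list
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ParameterError(f"unknown level {self.level!r}")
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}")
        if self.method == "remove" and self.level != "global":
            raise ParameterError("feature removal is only defined at the global level")

    def cell_mask(self, n: int, d: int) -> np.ndarray:
        """Boolean (n, d) mask of cells slated for corruption."""
        mask = np.zeros((n, d), dtype=bool)
        if self.level == "local":
            for i, feats in enumerate(self.selected):
                mask[i, np.asarray(feats, dtype=int)] = True
        elif self.level == "class":
            for g, feats in self.selected.items():
                rows = self.labels == g
                mask[np.ix_(rows, np.asarray(feats, dtype=int))] = True
        else:
            mask[:, np.asarray(self.selected, dtype=int)] = True
        return mask


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by ascending index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])


def select_features(
    scores: np.ndarray,
    level: str,
    fraction: float,
    labels: Sequence | None = None,
    method: str = "mean",
) -> CorruptionPlan:
    """Build a corruption plan from importance scores.

    ``scores`` is either an (n, d) per-sample matrix (e.g. |attributions|) or
    a length-d importance vector (higher = more important).  Per-sample
    matrices drive class/global selection by counting how often each feature
    enters a member sample's top-fraction set.
    """
    scores = np.asarray(scores, dtype=float)
    d = scores.shape[-1]
    k = int(round(fraction * d))
    if k < 1:
        raise ParameterError(
            f"fraction {fraction} selects round({fraction} * {d}) = 0 features"
        )
    if level == "local":
        if scores.ndim != 2:
            raise ParameterError("local selection needs per-sample scores")
        sel = np.stack([_top_k(row, k) for row in scores])
        return CorruptionPlan(level, method, fraction, sel)
    if scores.ndim == 1:
        top = _top_k(scores, k).tolist()
        if level == "global":
            return CorruptionPlan(level, method, fraction, top)
        if labels is None:
            raise ParameterError("class-level selection requires labels")
        labels = np.asarray(labels)
        return CorruptionPlan(
            level, method, fraction, {g: top for g in sorted(set(labels.tolist()))}, labels
        )
    per_sample = np.stack([_top_k(row, k) for row in scores])
    counts_for = lambda rows: np.bincount(per_sample[rows].ravel(), minlength=d)
    if level == "global":
        top = _top_k(counts_for(np.arange(scores.shape[0])).astype(float), k).tolist()
        return CorruptionPlan(level, method, fraction, top)
    if labels is None:
        raise ParameterError("class-level selection requires labels")
    labels = np.asarray(labels)
    sel = {}
    for g in sorted(set(labels.tolist())):
        rows = np.nonzero(labels == g)[0]
        sel[g] = _top_k(counts_for(rows).astype(float), k).tolist()
    return CorruptionPlan(level, method, fraction, sel, labels)


def corrupt(X: DataMatrix, plan: CorruptionPlan, seed: int = 0) -> DataMatrix:
    """Apply the plan: mean-replace, within-feature permute, or remove columns."""
    n, d = X.values.shape
    if plan.method == "remove":
        keep = [j for j in range(d) if j not in set(plan.selected)]
        if not keep:
            raise ParameterError("removal would delete every feature")
        return X.subset_features(keep)
    mask = plan.cell_mask(n, d)
    values = X.values.copy()
    rng = np.random.default_rng(seed)
    if plan.level == "class" and plan.labels is not None:
        scopes = [np.nonzero(plan.labels == g)[0] for g in sorted(set(plan.labels.tolist()))]
    else:
        scopes = [np.arange(n)]  # local and global average over the whole dataset
    for rows in scopes:
        sub = mask[rows]
        for j in range(d):
            cells = rows[sub[:, j]]
            if cells.size == 0:
                continue
            if plan.method == "mean":
                values[cells, j] = values[cells, j].mean()
            else:  # permute within feature across the unit's selected samples
                values[cells, j] = rng.permutation(values[cells, j])
    return DataMatrix(values, list(X.feature_names), list(X.sample_ids))


# ---------------------------------------------------------------------------
# degradation metrics


def metric_spearman(
    Y_before: np.ndarray,
    Y_after: np.ndarray,
    max_exact_n: int = 3000,
    n_pairs_subsample: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Spearman rank correlation of all pairwise embedded distances."""
    Y_before = np.asarray(Y_before, float)
    Y_after = np.asarray(Y_after, float)
    n = Y_before.shape[0]
    if Y_after.shape[0] != n:
        raise ParameterError("embeddings must have the same number of points")
    if n < 3:
        raise ParameterError("pairwise-distance correlation undefined for n < 3")
    if n <= max_exact_n:
        d1 = pdist(Y_before)
        d2 = pdist(Y_after)
    else:  # seeded subsample of pairs; desk-scale memory bound
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, n, size=n_pairs_subsample)
        jj = rng.integers(0, n, size=n_pairs_subsample)
        ok = ii != jj
        ii, jj = ii[ok], jj[ok]
        d1 = np.linalg.norm(Y_before[ii] - Y_before[jj], axis=1)
        d2 = np.linalg.norm(Y_after[ii] - Y_after[jj], axis=1)
    return float(spearmanr(d1, d2).statistic)


def _knn_sets(Y: np.ndarray, k: int) -> np.ndarray:
    """(n, k) neighbor indices, distance ties broken by ascending index."""
    from scipy.spatial.distance import squareform

    D = squareform(pdist(Y))
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def metric_knn10(Y_before: np.ndarray, Y_after: np.ndarray, k: int = 10) -> float:
    """Mean fraction of each point's k nearest neighbors retained."""
    n = np.asarray(Y_before).shape[0]
    if n <= k:
        raise ParameterError(f"k-NN preservation needs n > k = {k}")
    nb = _knn_sets(np.asarray(Y_before, float), k)
    na = _knn_sets(np.asarray(Y_after, float), k)
    overlap = [len(set(nb[i]) & set(na[i])) / k for i in range(n)]
    return float(np.mean(overlap))


def metric_ari_kmeans(
    Y_before: np.ndarray, Y_after: np.ndarray, K: int = 10, seed: int = 0
) -> float:
    """ARI between independent K-means clusterings of the two embeddings."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    Y_before = np.asarray(Y_before, float)
    Y_after = np.asarray(Y_after, float)
    if Y_before.shape[0] < K:
        raise ParameterError(f"K-means needs n >= K = {K}")
    km1 = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(Y_before)
    km2 = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(Y_after)
    return float(adjusted_rand_score(km1, km2))


# ---------------------------------------------------------------------------
# baseline importances


def laplacian_score(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Laplacian score of each feature on the affinity graph S (smaller = better).

    L_r = (f~' L f~) / (f~' D f~) with D = diag(S 1), L = D - S and f~ the
    D-weighted centering of the feature.
    """
    X = np.asarray(X, float)
    S = np.asarray(S, float)
    deg = S.sum(axis=1)
    total = deg.sum()
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j]
        f_t = f - (f @ deg) / total
        num = f_t @ (deg * f_t) - f_t @ (S @ f_t)  # f' (D - S) f
        den = f_t @ (deg * f_t)
        if den <= 1e-12 * max(1.0, f @ (deg * f)):
            scores[j] = np.inf  # constant feature: least informative
        else:
            scores[j] = num / den
    return scores


def fisher_score(X: np.ndarray, labels: Sequence) -> np.ndarray:
    """Fisher ratio of between-class to within-class variance (larger = better)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for g in sorted(set(labels.tolist())):
        rows = X[labels == g]
        n_g = rows.shape[0]
        num += n_g * (rows.mean(axis=0) - mu) ** 2
        den += n_g * rows.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[~np.isfinite(out)] = 0.0
    return out


def pca_variance_score(X: np.ndarray, explained_variance_target: float = 0.9) -> np.ndarray:
    """Variance-based control: sum over top PCs of lambda_c * loading_cf^2."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, float)
    pca = PCA().fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, explained_variance_target) + 1)
    lam = pca.explained_variance_[:m]
    comp = pca.components_[:m]
    return comp.T**2 @ lam


BASELINE_KINDS = (
    "laplace_P",
    "laplace_Q",
    "fisher",
    "pca_variance",
    "abs_feature",
    "attribution_times_feature",
    "random",
)


def baseline_scores(
    X: DataMatrix | np.ndarray,
    kind: str,
    labels: Sequence | None = None,
    affinity: np.ndarray | None = None,
    embedding: np.ndarray | None = None,
    attributions: np.ndarray | None = None,
    level: str = "global",
    perplexity: float = 30.0,
):
    """Importance scores for one baseline, oriented so higher = more important.

    ``laplace_P`` needs ``affinity`` (or calibrates it), ``laplace_Q`` needs
    the reference ``embedding``; ``fisher`` needs labels.  ``abs_feature``
    returns an (n, d) matrix at the local level and a mean-|x| vector
    otherwise.  ``random`` has no scores; draw plans via
    :func:`random_feature_plan`.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, float)
    if kind == "laplace_P":
        if affinity is None:
            affinity = calibrate_affinities(values, perplexity).P
        return -laplacian_score(values, affinity)
    if kind == "laplace_Q":
        if embedding is None:
            raise ParameterError("laplace_Q needs the reference embedding")
        U, Z, _ = student_t_kernel(np.asarray(embedding, float))
        return -laplacian_score(values, U / Z)
    if kind == "fisher":
        if labels is None:
            raise ParameterError("fisher score requires labels")
        return fisher_score(values, labels)
    if kind == "pca_variance":
        return pca_variance_score(values)
    if kind == "abs_feature":
        return np.abs(values) if level == "local" else np.abs(values).mean(axis=0)
    if kind == "attribution_times_feature":
        if attributions is None:
            raise ParameterError("attribution_times_feature needs attributions")
        return np.abs(np.asarray(attributions) * values)
    raise ParameterError(f"unknown baseline kind {kind!r}")


def class_laplacian_scores(
    X: DataMatrix | np.ndarray,
    labels: Sequence,
    matrix: str = "P",
    perplexity: float = 30.0,
    tsne_config: OptimizerConfig | None = None,
    seed: int = 0,
) -> dict:
    """Class-based Laplacian scores: P and Q recomputed on each class subset."""
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, float)
    labels = np.asarray(labels)
    out = {}
    for g in sorted(set(labels.tolist())):
        sub = values[labels == g]
        perp = min(perplexity, sub.shape[0] - 1)
        if matrix == "P":
            S = calibrate_affinities(sub, perp).P
        else:
            cfg = tsne_config or OptimizerConfig(n_iter=300, exaggeration_iters=100)
            res = fit(sub, cfg, perplexity=perp, seed=seed)
            U, Z, _ = student_t_kernel(res.Y)
            S = U / Z
        out[g] = -laplacian_score(sub, S)
    return out


def random_feature_plan(
    d: int,
    level: str,
    fraction: float,
    method: str,
    seed: int,
    n_samples: int | None = None,
    labels: Sequence | None = None,
) -> CorruptionPlan:
    """One seeded random subset plan (a different subset per sample/class
    at the local/class level, one shared subset globally)."""
    k = int(round(fraction * d))
    if k < 1:
        raise ParameterError("fraction selects zero features")
    rng = np.random.default_rng(seed)
    if level == "local":
        sel = np.stack([np.sort(rng.choice(d, size=k, replace=False)) for _ in range(n_samples)])
        return CorruptionPlan(level, method, fraction, sel)
    if level == "class":
        labels = np.asarray(labels)
        sel = {
            g: np.sort(rng.choice(d, size=k, replace=False)).tolist()
            for g in sorted(set(labels.tolist()))
        }
        return CorruptionPlan(level, method, fraction, sel, labels)
    return CorruptionPlan(level, method, fraction, np.sort(rng.choice(d, size=k, replace=False)).tolist())


# ---------------------------------------------------------------------------
# the experiment driver


@dataclasses.dataclass
class ValidationReport:
    """Flat per-cell metric table plus aggregation with bootstrap CIs."""

    cells: pd.DataFrame
    metadata: dict

    def summary(self, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Mean and percentile 95% bootstrap CI per experimental cell."""
        rng = np.random.default_rng(seed)
        rows = []
        group_cols = ["selector", "level", "method", "fraction"]
        for key, grp in self.cells.groupby(group_cols):
            row = dict(zip(group_cols, key))
            for metric in ("spearman", "ari", "knn10"):
                vals = grp[metric].values
                row[metric] = float(np.mean(vals))
                if vals.size > 1:
                    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
                    means = vals[idx].mean(axis=1)
                    row[f"{metric}_lo"] = float(np.percentile(means, 2.5))
                    row[f"{metric}_hi"] = float(np.percentile(means, 97.5))
                else:
                    row[f"{metric}_lo"] = row[f"{metric}_hi"] = row[metric]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "cells": self.cells.to_dict(orient="records"),
            "summary": self.summary().to_dict(orient="records"),
        }


def _metrics(Y_ref, Y_new, K, seed) -> dict:
    return {
        "spearman": metric_spearman(Y_ref, Y_new),
        "ari": metric_ari_kmeans(Y_ref, Y_new, K=K, seed=seed),
        "knn10": metric_knn10(Y_ref, Y_new),
    }


def run_experiment(
    X: DataMatrix | np.ndarray,
    labels: Sequence | None = None,
    selectors: Sequence[str] = ("attribution", "random"),
    levels: Sequence[str] = ("global",),
    methods: Sequence[str] = ("mean",),
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_tsne_seeds: int = 10,
    perplexity: float = 30.0,
    tsne_config: OptimizerConfig | None = None,
    seed: int = 0,
    n_random_subsets: int = 10,
    kmeans_k: int | None = None,
    on_error: str = "raise",
) -> ValidationReport:
    """Full corruption experiment over a selector x level x method x fraction grid.

    For every t-SNE seed: fit the reference embedding (tracked when a
    selector needs attributions), select features, corrupt, refit on the
    corrupted data with a fresh perplexity calibration but the same
    embedding-init seed, and compare embeddings with the three metrics.

    ``on_error="partial"`` records failed cells as NaN rows with the error
    message instead of aborting the grid; since every cell is deterministic
    in (seed, subset), a rerun reproduces and resumes the same grid.
    """
    if on_error not in ("raise", "partial"):
        raise ParameterError("on_error must be 'raise' or 'partial'")
    if not isinstance(X, DataMatrix):
        X = DataMatrix.from_values(np.asarray(X, float))
    labels_arr = None if labels is None else np.asarray(labels)
    config = tsne_config or OptimizerConfig()
    if kmeans_k is None:
        kmeans_k = len(set(labels_arr.tolist())) if labels_arr is not None else 10
    attr_kinds = {"attribution", "positive", "attribution_times_feature"}
    needs_attr = bool(attr_kinds & set(selectors))
    records = []
    for s in range(n_tsne_seeds):
        tsne_seed = seed + s
        if needs_attr:
            res = fit_attributions(X, config, perplexity=perplexity, seed=tsne_seed)
            Y_ref = res.Y
            A_raw = res.attributions("raw").A
        else:
            res = fit(X, config, perplexity=perplexity, seed=tsne_seed)
            Y_ref = res.Y
            A_raw = None
        score_of = {}
        for sel in selectors:
            if sel == "attribution":
                score_of[sel] = np.abs(A_raw)
            elif sel == "positive":
                score_of[sel] = np.where(A_raw > 0, A_raw, 0.0)
            elif sel == "attribution_times_feature":
                score_of[sel] = np.abs(A_raw * X.values)
            elif sel == "random":
                score_of[sel] = None
            elif sel in ("laplace_P", "laplace_Q", "fisher", "pca_variance", "abs_feature"):
                score_of[sel] = baseline_scores(
                    X,
                    sel,
                    labels=labels_arr,
                    embedding=Y_ref,
                    perplexity=perplexity,
                )
            else:
                raise ParameterError(f"unknown selector {sel!r}")
        for level, method, frac in itertools.product(levels, methods, fractions):
            for sel in selectors:
                if sel == "random":
                    for r in range(n_random_subsets):
                        plan = random_feature_plan(
                            X.d, level, frac, method,
                            seed=seed * 100003 + s * 1009 + r,
                            n_samples=X.n, labels=labels_arr,
                        )
                        rec = _guarded_cell(X, plan, config, perplexity, tsne_seed,
                                            Y_ref, kmeans_k, on_error)
                        rec.update(selector=sel, level=level, method=method,
                                   fraction=frac, tsne_seed=tsne_seed, subset=r)
                        records.append(rec)
                    continue
                if sel in ("laplace_P", "laplace_Q") and level == "class":
                    # class-based Laplacian: affinities recomputed per class
                    key = (sel, "class")
                    if key not in score_of:
                        score_of[key] = class_laplacian_scores(
                            X, labels_arr, matrix=sel[-1], perplexity=perplexity,
                            tsne_config=config, seed=tsne_seed,
                        )
                    k = int(round(frac * X.d))
                    if k < 1:
                        raise ParameterError(f"fraction {frac} selects zero features")
                    plan = CorruptionPlan(
                        level, method, frac,
                        {g: _top_k(v, k).tolist() for g, v in score_of[key].items()},
                        labels_arr,
                    )
                else:
                    plan = select_features(score_of[sel], level, frac, labels=labels_arr, method=method)
                rec = _guarded_cell(X, plan, config, perplexity, tsne_seed,
                                    Y_ref, kmeans_k, on_error)
                rec.update(selector=sel, level=level, method=method,
                           fraction=frac, tsne_seed=tsne_seed, subset=None)
                records.append(rec)
    cells = pd.DataFrame(records)
    meta = {
        "n": X.n, "d": X.d, "perplexity": perplexity, "seed": seed,
        "n_tsne_seeds": n_tsne_seeds, "kmeans_k": kmeans_k,
        "n_random_subsets": n_random_subsets,
        "n_iter": config.n_iter,
        "fractions": [float(f) for f in fractions],
    }
    return ValidationReport(cells=cells, metadata=meta)


def _guarded_cell(X, plan, config, perplexity, tsne_seed, Y_ref, kmeans_k, on_error) -> dict:
    if on_error == "raise":
        return _run_cell(X, plan, config, perplexity, tsne_seed, Y_ref, kmeans_k)
    try:
        return _run_cell(X, plan, config, perplexity, tsne_seed, Y_ref, kmeans_k)
    except Exception as exc:  # recorded, not fatal
        return {"spearman": np.nan, "ari": np.nan, "knn10": np.nan, "error": str(exc)}


def _run_cell(X, plan, config, perplexity, tsne_seed, Y_ref, kmeans_k) -> dict:
    Xc = corrupt(X, plan, seed=tsne_seed)
    perp = min(perplexity, Xc.n - 1)
    res = fit(Xc, config, perplexity=perp, seed=tsne_seed)
    return _metrics(Y_ref, res.Y, kmeans_k, tsne_seed)
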