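"""Sample clustering on the factorized embedding and its evaluation.

Samples are clustered in the k-dimensional coefficient embedding (the
columns of V) with normalized-cut spectral clustering; the number of
clusters is chosen by the mean silhouette over a candidate range (default
2..5). A k-means-on-raw-data baseline and a plain-NMF baseline support the
method comparison, and a two-group differential screen (Welch t or
Mann-Whitney, unadjusted p < alpha by default) characterizes the resulting
subtypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import false_discovery_control, mannwhitneyu, ttest_ind
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score

from .errors import ParameterError, UndefinedMetricError, ValidationError
from .factorization import (
    Hyperparameters,
    fit_dlonmf,
    fit_nmf,
    reconstruction_pcc,
    relative_error,
)
from .graphs import laplacian_pair_for
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_C_VALUES: tuple[int, ...] = (2, 3, 4, 5)


@dataclass
class ClusteringResult:
    """Sample labels with their silhouette evaluation."""

    labels: np.ndarray
    c: int
    silhouette_per_sample: np.ndarray
    mean_silhouette: float
    method: Literal["spectral", "kmeans"]
    embedding_source: Literal["V-columns", "raw-X"]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.c)):
            raise ValidationError(
                f"labels must cover 0..{self.c - 1}; found {present.tolist()}"
            )


def silhouette(
    points: np.ndarray, labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Per-sample and mean silhouette, Euclidean distance.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) where a(i) is the mean distance
    from i to the other members of its own cluster and b(i) the minimum over
    other clusters of the mean distance to that cluster's members. Samples
    in singleton clusters get s(i) = 0 by convention, as do pairs at zero
    distance scale (max(a, b) = 0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and np.asarray(labels).size > 1:
        points = points.T  # 1-D point list passed as a row
    labels = np.asarray(labels)
    if labels.shape[0] != points.shape[0]:
        raise ParameterError(
            f"{labels.shape[0]} labels for {points.shape[0]} points"
        )
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise UndefinedMetricError("silhouette requires at least 2 clusters")

    dist = cdist(points, points)
    q = points.shape[0]
    s = np.zeros(q)
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    for i in range(q):
        own = members[labels[i]]
        if own.size == 1:
            continue  # singleton convention: s = 0
        a = dist[i, own].sum() / (own.size - 1)
        b = min(dist[i, members[c]].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return s, float(s.mean())


def _spectral_n_neighbors(n: int) -> int:
    # n/10 capped at 10, but never below 5: fewer neighbors fragments the
    # affinity graph of small sample sets into spurious components
    return min(10, max(5, n // 10), n - 1)


def spectral_cluster(V: np.ndarray, c: int, seed: int = 0) -> np.ndarray:
    """Normalized-cut spectral clustering of the n columns of V into c groups.

    Uses a kNN affinity (k = min(10, n/10), floored at 5), the normalized
    Laplacian's leading eigenvectors and seeded k-means on them.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    points = V.T  # samples as rows
    n = points.shape[0]
    if c > n:
        raise ParameterError(f"c={c} exceeds number of samples {n}")
    if c < 2:
        raise ParameterError(f"spectral clustering needs c >= 2, got {c}")
    if c == n:
        return np.arange(n)
    model = SpectralClustering(
        n_clusters=c,
        affinity="nearest_neighbors",
        n_neighbors=_spectral_n_neighbors(n),
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    with warnings.catch_warnings():
        # disconnected kNN graphs are expected for well-separated clusters
        warnings.filterwarnings("ignore", message=".*not fully connected.*")
        labels = model.fit_predict(points)
    return _canonical_labels(labels)


def kmeans_cluster(points: np.ndarray, c: int, seed: int = 0) -> np.ndarray:
    """Lloyd k-means with 10 seeded restarts, best inertia kept."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    q = points.shape[0]
    if c > q:
        raise ParameterError(f"c={c} exceeds number of points {q}")
    if c < 1:
        raise ParameterError(f"c must be >= 1, got {c}")
    if c == 1:
        return np.zeros(q, dtype=int)
    model = KMeans(n_clusters=c, n_init=10, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Number of distinct clusters.*")
        labels = model.fit_predict(points)
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters to consecutive ints in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(labels.shape[0], dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def choose_cluster_number(
    V: np.ndarray,
    c_values: Sequence[int] = DEFAULT_C_VALUES,
    seed: int = 0,
) -> tuple[int, list[tuple[int, float]]]:
    """Spectral-cluster V's columns for each candidate c; pick max silhouette.

    Ties go to the smaller c. Returns (best_c, [(c, mean_silhouette), ...]).
    """
    if not len(c_values):
        raise ParameterError("c_values must be non-empty")
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n = V.shape[1]
    per_c: list[tuple[int, float]] = []
    for c in c_values:
        c = int(c)
        if not 2 <= c <= n - 1:
            raise ParameterError(f"c={c} outside valid range [2, {n - 1}]")
        labels = spectral_cluster(V, c, seed)
        _, mean_s = silhouette(V.T, labels)
        per_c.append((c, mean_s))
    best_c = max(per_c, key=lambda t: (t[1], -t[0]))[0]
    return best_c, per_c


def cluster_samples(
    V: np.ndarray, c: int, seed: int = 0
) -> ClusteringResult:
    """Spectral-cluster V's columns into c groups and attach silhouettes."""
    labels = spectral_cluster(V, c, seed)
    per_sample, mean_s = silhouette(np.atleast_2d(V).T, labels)
    return ClusteringResult(
        labels=labels,
        c=int(np.unique(labels).size),
        silhouette_per_sample=per_sample,
        mean_silhouette=mean_s,
        method="spectral",
        embedding_source="V-columns",
    )


def benchmark_methods(
    X: ExpressionMatrix | np.ndarray,
    hp: Hyperparameters,
    c_values: Sequence[int] = DEFAULT_C_VALUES,
    seed: int = 0,
    true_labels: Sequence[int] | None = None,
    k_feat: int = 5,
    k_sample: int = 5,
) -> pd.DataFrame:
    """Compare plain NMF, raw-data k-means and DL-ONMF across cluster counts.

    Factor methods are spectral-clustered in their V embedding; k-means runs
    directly on the sample columns of X. Reconstruction metrics apply to the
    factor methods only. ARI columns appear when ground truth is supplied.
    """
    if isinstance(X, ExpressionMatrix):
        Xm = X
    else:
        Xa = np.asarray(X, dtype=float)
        Xm = ExpressionMatrix(
            Xa,
            [f"gene_{i + 1}" for i in range(Xa.shape[0])],
            [f"sample_{j + 1}" for j in range(Xa.shape[1])],
        )
    feature_graph, sample_graph = laplacian_pair_for(Xm, k_feat, k_sample)

    nmf_model = fit_nmf(Xm, hp.k, hp.n_iter, seed)
    dlonmf_model = fit_dlonmf(Xm, feature_graph, sample_graph, replace(hp, seed=seed))

    rows = []
    for c in c_values:
        c = int(c)
        for method, model in (("NMF", nmf_model), ("DL-ONMF", dlonmf_model)):
            labels = spectral_cluster(model.V, c, seed)
            _, mean_s = silhouette(model.V.T, labels)
            row = {
                "method": method,
                "c": c,
                "reconstruction_pcc": reconstruction_pcc(Xm, model.U, model.V),
                "relative_error": relative_error(Xm, model.U, model.V),
                "mean_silhouette": mean_s,
            }
            if true_labels is not None:
                row["ari"] = adjusted_rand_score(true_labels, labels)
            rows.append(row)
        km_labels = kmeans_cluster(Xm.values.T, c, seed)
        _, km_s = silhouette(Xm.values.T, km_labels)
        row = {
            "method": "K-means",
            "c": c,
            "reconstruction_pcc": np.nan,
            "relative_error": np.nan,
            "mean_silhouette": km_s,
        }
        if true_labels is not None:
            row["ari"] = adjusted_rand_score(true_labels, km_labels)
        rows.append(row)
    return pd.DataFrame(rows)


def differential_expression(
    X: ExpressionMatrix | np.ndarray,
    labels: Sequence[int],
    test: Literal["welch-t", "wilcoxon"] = "welch-t",
    alpha: float = 0.05,
    adjust: Literal[None, "bh"] = None,
) -> pd.DataFrame:
    """Per-gene two-sided test between exactly two sample groups.

    log_fc is mean(group1) - mean(group2), i.e. expression values are
    assumed log-scale. P-values are unadjusted by default;
    ``adjust='bh'`` adds a Benjamini-Hochberg column and flags on it.
    """
    if isinstance(X, ExpressionMatrix):
        values, gene_ids = X.values, X.gene_ids
    else:
        values = np.asarray(X, dtype=float)
        gene_ids = [f"gene_{i + 1}" for i in range(values.shape[0])]
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[1]:
        raise ParameterError(
            f"{labels.shape[0]} labels for {values.shape[1]} samples"
        )
    groups = np.unique(labels)
    if groups.size != 2:
        raise ParameterError(f"exactly 2 groups required, found {groups.size}")
    g1 = values[:, labels == groups[0]]
    g2 = values[:, labels == groups[1]]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ParameterError("each group needs at least 2 samples")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")

    mean1 = g1.mean(axis=1)
    mean2 = g2.mean(axis=1)
    if test == "welch-t":
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, pval = ttest_ind(g1, g2, axis=1, equal_var=False)
        degenerate = ~np.isfinite(pval)
        if degenerate.any():
            logger.warning(
                "%d zero-variance genes: p set to 1", int(degenerate.sum())
            )
            stat = np.where(degenerate, 0.0, stat)
            pval = np.where(degenerate, 1.0, pval)
    elif test == "wilcoxon":
        stat = np.empty(values.shape[0])
        pval = np.empty(values.shape[0])
        for i in range(values.shape[0]):
            try:
                res = mannwhitneyu(g1[i], g2[i], alternative="two-sided")
                stat[i], pval[i] = res.statistic, res.pvalue
            except ValueError:  # all values identical
                stat[i], pval[i] = 0.0, 1.0
    else:
        raise ParameterError(f"unknown test {test!r}")

    log_fc = mean1 - mean2
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group1_mean": mean1,
            "group2_mean": mean2,
            "log_fc": log_fc,
            "statistic": stat,
            "p_value": pval,
            "direction": np.where(log_fc > 0, "up", "down"),
        }
    )
    if adjust == "bh":
        table["p_adjusted"] = false_discovery_control(table["p_value"], method="bh")
        table["significant"] = table["p_adjusted"] < alpha
    elif adjust is None:
        table["significant"] = table["p_value"] < alpha
    else:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    return table
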