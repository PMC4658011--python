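"""Unsupervised analysis of BPE texture: z-scoring and 2-partition k-means.

Cases are clustered on their background parenchymal enhancement (BPE) texture
features alone, without subtype labels, to test whether BPE heterogeneity
groups triple-negative cases together: features are standardized to z-scores
across cases, Lloyd's k-means (k = 2, Euclidean, k-means++ init, best of 50
restarts by inertia) partitions the cases, and the composition report counts
positives per partition with a descriptive Fisher exact p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans

from .errors import DegenerateClusteringError, RadbpeError
from .tables import FeatureTable


@dataclass
class ClusterResult:
    """Two-partition k-means output over the z-scored feature matrix."""

    assignments: np.ndarray  # partition index (0/1) per case
    inertia: float
    centers: np.ndarray
    matrix: pd.DataFrame  # the z-scored matrix that was clustered
    restarts: int

    def __post_init__(self) -> None:
        if len(np.unique(self.assignments)) != 2:
            raise RadbpeError("expected exactly 2 non-empty partitions")


def zscore_normalize(table: FeatureTable, scope="bpe") -> pd.DataFrame:
    """Standardize the scope's columns to z-scores across cases.

    Uses the sample (n−1) standard deviation.  Zero-variance columns are
    dropped with a warning; if all columns are constant the input carries no
    structure to cluster and an error is raised.
    """
    cols = table.scope_columns(scope)
    if table.n_cases < 2:
        raise RadbpeError("z-scoring needs at least 2 cases")
    frame = table.frame[cols]
    sd = frame.std(ddof=1)
    keep = sd[sd > 0].index
    if len(keep) == 0:
        raise DegenerateClusteringError("all columns are constant")
    if len(keep) < len(cols):
        warnings.warn(f"dropping {len(cols) - len(keep)} zero-variance column(s)",
                      stacklevel=2)
    z = (frame[keep] - frame[keep].mean()) / sd[keep]
    return z


def kmeans_partition(matrix: pd.DataFrame, restarts: int = 50, seed: int = 0) -> ClusterResult:
    """Best-of-``restarts`` two-means clustering of the case × feature matrix."""
    x = np.asarray(matrix, dtype=np.float64)
    if len(x) < 2:
        raise RadbpeError("k-means with k=2 needs at least 2 cases")
    km = KMeans(n_clusters=2, n_init=restarts, init="k-means++", random_state=seed)
    assignments = km.fit_predict(x)
    return ClusterResult(
        assignments=assignments,
        inertia=float(km.inertia_),
        centers=km.cluster_centers_,
        matrix=matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(x),
        restarts=restarts,
    )


def partition_composition(result: ClusterResult, labels: np.ndarray) -> dict:
    """Per-partition positive/negative counts and enrichment summary.

    The enriched partition is the one with the larger positive fraction
    (invariant to partition index swaps).  The Fisher exact p-value is
    descriptive output, not a selection criterion.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(result.assignments):
        raise RadbpeError("labels and assignments differ in length")
    counts = np.zeros((2, 2), dtype=int)  # [partition, class]
    for part in (0, 1):
        sel = result.assignments == part
        counts[part, 1] = int(labels[sel].sum())
        counts[part, 0] = int(np.sum(sel) - counts[part, 1])
    frac = [counts[p, 1] / counts[p].sum() for p in (0, 1)]
    enriched = int(np.argmax(frac))
    _, p = fisher_exact(counts)
    return {
        "counts": {f"partition_{p_}": {"positive": int(counts[p_, 1]),
                                       "negative": int(counts[p_, 0])}
                   for p_ in (0, 1)},
        "enriched_partition": enriched,
        "positives_in_enriched": int(counts[enriched, 1]),
        "total_positives": int(labels.sum()),
        "fisher_p": float(p),
    }


def cluster_bpe(table: FeatureTable, restarts: int = 50, seed: int = 0) -> tuple[ClusterResult, dict]:
    """Convenience chain: z-score BPE columns, cluster, summarize composition."""
    z = zscore_normalize(table, scope="bpe")
    result = kmeans_partition(z, restarts=restarts, seed=seed)
    return result, partition_composition(result, table.labels)
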