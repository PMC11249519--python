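"""Classifier features: normalized subtype-specific read counts pooled over
size-constrained marker clusters.

A sample's qualifying-fragment count at a marker (alpha beyond the marker's
inclusive threshold) is depth-normalized as ``1e9 * count / total mapped
fragments``.  Markers of one (class, direction) cell are grouped into
clusters of 45-55 by constrained K-means; one feature per cluster is
``ln(mean normalized count over members + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .types import Marker, MergedMarker, SampleFragments, ValidationError

MIN_CLUSTER_SIZE = 45
MAX_CLUSTER_SIZE = 55
NORMALIZATION_SCALE = 1e9


def normalize_count(count: float, total_fragments: int) -> float:
    """Depth-normalized read count: 1e9 * count / genome-wide fragments."""
    if total_fragments <= 0:
        raise ValidationError("total_fragments must be positive")
    return NORMALIZATION_SCALE * count / total_fragments


def marker_read_count(
    sample: SampleFragments, marker: Marker, min_cpgs: int = 1
) -> int:
    """Number of the sample's fragments qualifying at the marker."""
    alphas = sample.region_alphas(marker.region_id, min_cpgs=min_cpgs)
    if marker.direction == "hypo":
        return int((alphas <= marker.alpha_threshold).sum())
    return int((alphas >= marker.alpha_threshold).sum())


def marker_count_table(
    cohort: list[SampleFragments], markers: list[Marker], min_cpgs: int = 1
) -> pd.DataFrame:
    """Qualifying-fragment counts, samples x markers (column = marker_id)."""
    mdf = pd.DataFrame(
        {
            "region_id": [m.region_id for m in markers],
            "midx": np.arange(len(markers)),
            "is_hypo": [m.direction == "hypo" for m in markers],
            "thr": [m.alpha_threshold for m in markers],
        }
    )
    rows = np.zeros((len(cohort), len(markers)), dtype=np.int64)
    for si, sample in enumerate(cohort):
        f = sample.frame
        if min_cpgs > 1:
            f = f[f["n_cpgs"] >= min_cpgs]
        if not len(f):
            continue
        merged = pd.DataFrame(
            {
                "region_id": f["region_id"].astype(str).to_numpy(),
                "alpha": f["n_methylated"].to_numpy(float)
                / f["n_cpgs"].to_numpy(float),
            }
        ).merge(mdf, on="region_id")
        if not len(merged):
            continue
        alpha = merged["alpha"].to_numpy()
        thr = merged["thr"].to_numpy()
        qual = np.where(merged["is_hypo"].to_numpy(), alpha <= thr, alpha >= thr)
        rows[si] = np.bincount(
            merged["midx"].to_numpy()[qual], minlength=len(markers)
        )
    return pd.DataFrame(
        rows,
        index=[s.sample_id for s in cohort],
        columns=[m.marker_id for m in markers],
    )


def normalized_count_table(
    cohort: list[SampleFragments], markers: list[Marker], min_cpgs: int = 1
) -> pd.DataFrame:
    counts = marker_count_table(cohort, markers, min_cpgs=min_cpgs)
    totals = np.array([s.total_fragments for s in cohort], dtype=float)
    return counts * (NORMALIZATION_SCALE / totals[:, None])


# ---------------------------------------------------------------------------
# size-constrained K-means
# ---------------------------------------------------------------------------

def feasible_cluster_range(n: int, min_size: int = MIN_CLUSTER_SIZE,
                           max_size: int = MAX_CLUSTER_SIZE) -> tuple[int, int]:
    """Feasible cluster-count interval [ceil(n/max), floor(n/min)]."""
    return math.ceil(n / max_size), math.floor(n / min_size)


def _bounded_assignment(
    d2: np.ndarray, k: int, min_size: int, max_size: int
) -> np.ndarray:
    """Assign points to clusters under size bounds via two-phase matching.

    Phase 1 fills every cluster's ``min_size`` mandatory slots with the
    globally cheapest distinct points (rectangular Hungarian); phase 2
    assigns the remaining points to optional slots capped at ``max_size``.
    """
    n = d2.shape[0]
    slot_cluster = np.repeat(np.arange(k), min_size)
    row_ind, col_ind = linear_sum_assignment(d2[:, slot_cluster].T)
    labels = np.full(n, -1, dtype=int)
    labels[col_ind] = slot_cluster[row_ind]
    rest = np.flatnonzero(labels < 0)
    if rest.size:
        opt_cluster = np.repeat(np.arange(k), max_size - min_size)
        r, c = linear_sum_assignment(d2[np.ix_(rest, opt_cluster)])
        labels[rest[r]] = opt_cluster[c]
    return labels


def constrained_kmeans(
    X: np.ndarray,
    seed: int,
    min_size: int = MIN_CLUSTER_SIZE,
    max_size: int = MAX_CLUSTER_SIZE,
    n_clusters: int | None = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Partition rows of ``X`` into clusters with sizes in [min, max].

    The cluster count defaults to ``round(n / midpoint)`` clipped to the
    feasible interval.  Each iteration re-solves the size-bounded
    assignment and recomputes centroids; the loop stops at convergence or
    after ``max_iter`` iterations.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < min_size:
        raise ValidationError(
            f"cannot cluster {n} items with minimum cluster size {min_size}"
        )
    k_lo, k_hi = feasible_cluster_range(n, min_size, max_size)
    if k_lo > k_hi:
        raise ValidationError(
            f"no cluster count satisfies size bounds [{min_size}, {max_size}] "
            f"for n={n}"
        )
    if n_clusters is None:
        mid = (min_size + max_size) / 2
        n_clusters = int(np.clip(round(n / mid), k_lo, k_hi))
    elif not k_lo <= n_clusters <= k_hi:
        raise ValidationError(
            f"n_clusters={n_clusters} outside feasible range [{k_lo}, {k_hi}]"
        )

    rng = np.random.default_rng(seed)
    # k-means++ seeding
    centers = [X[rng.integers(n)]]
    for _ in range(1, n_clusters):
        d2 = np.min(cdist(X, np.array(centers), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    centers = np.array(centers)

    labels = np.full(n, -1, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = _bounded_assignment(d2, n_clusters, min_size, max_size)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(n_clusters):
            members = X[labels == c]
            if len(members):
                centers[c] = members.mean(axis=0)
    sizes = np.bincount(labels, minlength=n_clusters)
    assert ((sizes >= min_size) & (sizes <= max_size)).all()
    return labels


def build_merged_markers(
    markers: list[Marker],
    reference_cohort: list[SampleFragments],
    seed: int,
    min_size: int = MIN_CLUSTER_SIZE,
    max_size: int = MAX_CLUSTER_SIZE,
    min_cpgs: int = 1,
) -> list[MergedMarker]:
    """Cluster each (class, direction) cell of markers into merged markers.

    The clustering space is each marker's vector of ln(normalized count
    + 1) across the reference (discovery tissue) samples, so markers that
    co-behave across training samples are pooled.
    """
    profile = np.log1p(
        normalized_count_table(reference_cohort, markers, min_cpgs=min_cpgs)
        .to_numpy()
        .T
    )  # markers x samples
    merged: list[MergedMarker] = []
    for cls in ("LUAD", "LUSC"):
        for direction in ("hypo", "hyper"):
            idx = [
                i
                for i, m in enumerate(markers)
                if m.target_class == cls and m.direction == direction
            ]
            if not idx:
                continue
            labels = constrained_kmeans(
                profile[idx], seed=seed, min_size=min_size, max_size=max_size
            )
            for c in range(labels.max() + 1):
                members = tuple(
                    markers[idx[j]].marker_id for j in np.flatnonzero(labels == c)
                )
                mm = MergedMarker(
                    merged_id=f"{cls}_{direction}_{c:03d}",
                    target_class=cls,
                    direction=direction,
                    members=members,
                )
                mm.check_invariants(min_size, max_size)
                merged.append(mm)
    return merged


def build_feature_matrix(
    cohort: list[SampleFragments],
    markers: list[Marker],
    merged: list[MergedMarker],
    min_cpgs: int = 1,
) -> pd.DataFrame:
    """Feature matrix, samples x merged markers: ln(mean normalized count + 1)."""
    norm = normalized_count_table(cohort, markers, min_cpgs=min_cpgs)
    cols = {}
    for mm in merged:
        cols[mm.merged_id] = np.log1p(norm[list(mm.members)].mean(axis=1))
    return pd.DataFrame(cols, index=norm.index)


def build_feature_vector(
    sample: SampleFragments,
    markers: list[Marker],
    merged: list[MergedMarker],
    min_cpgs: int = 1,
) -> pd.Series:
    return build_feature_matrix([sample], markers, merged, min_cpgs=min_cpgs).iloc[0]
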