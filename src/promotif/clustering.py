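"""Expression-profile clustering and reversal-pattern selection.

Genes in the differentially expressed universe are summarized by their
(control, MCAO, MCAO_NRG1) group-mean triple, standardized to shape
(row mean 0, population sd 1), partitioned with k-means (k = 10 by default),
and each cluster centroid is classified as a *reversal* pattern — shifted by
injury and moved back toward baseline by treatment — or not. Reversal
clusters above a minimum size are carried forward to the promoter stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import GROUPS, _check_design


@dataclass
class ProfileMatrix:
    """Per-gene group-mean triples and (optionally) their standardized form.

    ``constant_genes`` lists genes whose raw triple was constant: they cannot
    be standardized and are excluded from ``standardized``.
    """

    profiles: pd.DataFrame  # genes x GROUPS, log2 units
    standardized: pd.DataFrame | None = None
    constant_genes: list[str] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    labels: "pd.Series[int]"  # gene -> cluster id in 1..k
    centroids: pd.DataFrame  # cluster id x GROUPS
    objective: float  # sum of squared distances (best over restarts)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])

    def sizes(self) -> "pd.Series[int]":
        return self.labels.value_counts().reindex(self.centroids.index, fill_value=0)


@dataclass(frozen=True)
class PatternLabel:
    """Reversal classification of a centroid triple (c, m, n).

    ``effect`` is the injury shift m - c; ``recovery`` is the fraction of that
    shift undone by treatment, r = (n - m) / (c - m).
    """

    label: str  # reversal_down | reversal_up | other
    effect: float
    recovery: float


def group_mean_profiles(
    matrix: pd.DataFrame, design: Mapping[str, str], genes: Sequence[str]
) -> ProfileMatrix:
    """Arithmetic group means per gene, in (control, MCAO, MCAO_NRG1) order."""
    design = _check_design(matrix, design)
    unknown = [g for g in genes if g not in matrix.index]
    if unknown:
        raise KeyError(f"genes absent from expression matrix: {unknown[:5]}")
    sub = matrix.loc[list(genes)]
    cols = {g: sub.loc[:, (design == g).to_numpy()].mean(axis=1) for g in GROUPS}
    return ProfileMatrix(profiles=pd.DataFrame(cols, columns=list(GROUPS)))


def standardize(pm: ProfileMatrix) -> ProfileMatrix:
    """Standardize each row to mean 0, population sd 1 (over the 3 values).

    Constant rows cannot be standardized; they are dropped from the
    standardized frame, recorded in ``constant_genes`` and warned about.
    """
    x = pm.profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd
    const = sd[:, 0] <= 1e-12
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant profile(s) excluded from standardization",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    std = pd.DataFrame(z[~const], index=pm.profiles.index[~const], columns=pm.profiles.columns)
    return ProfileMatrix(
        profiles=pm.profiles,
        standardized=std,
        constant_genes=list(pm.profiles.index[const]),
    )


def kmeans_cluster(
    profiles: pd.DataFrame, k: int, seed: int, n_restarts: int = 25
) -> ClusterAssignment:
    """k-means partition of profile rows (Lloyd, k-means++, best of restarts).

    Deterministic given ``seed``; cluster ids are 1..k.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of genes ({len(profiles)})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=300,
        random_state=seed,
        algorithm="lloyd",
    )
    labels = km.fit_predict(profiles.to_numpy(dtype=float))
    return ClusterAssignment(
        labels=pd.Series(labels + 1, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(
            km.cluster_centers_, index=range(1, k + 1), columns=profiles.columns
        ),
        objective=float(km.inertia_),
    )


def classify_pattern(
    centroid: Sequence[float], delta: float = 0.5, rho: float = 0.5
) -> PatternLabel:
    """Classify a (control, MCAO, MCAO_NRG1) centroid triple.

    reversal_down: injury shift m - c <= -delta and recovery r >= rho;
    reversal_up:   m - c >= +delta and r >= rho; otherwise ``other``.
    r = (n - m)/(c - m) is the fraction of the injury shift undone by
    treatment (1 = full return to baseline, negative = moved further away).
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    c, m, n = (float(v) for v in centroid)
    effect = m - c
    recovery = (n - m) / (c - m) if c != m else 0.0
    if effect <= -delta and recovery >= rho:
        label = "reversal_down"
    elif effect >= delta and recovery >= rho:
        label = "reversal_up"
    else:
        label = "other"
    return PatternLabel(label=label, effect=effect, recovery=recovery)


def select_reversal_clusters(
    assignment: ClusterAssignment,
    labels: Mapping[int, PatternLabel],
    min_size: int = 10,
) -> list[int]:
    """Reversal clusters with size strictly greater than ``min_size``.

    Ordered by |injury effect| descending. The strict inequality reproduces
    the exclusion of a 10-gene reversal cluster at the default min_size of 10.
    """
    missing = [c for c in assignment.centroids.index if c not in labels]
    if missing:
        raise ValueError(f"no pattern label for cluster(s) {missing}")
    sizes = assignment.sizes()
    chosen = [
        cid
        for cid in assignment.centroids.index
        if labels[cid].label.startswith("reversal") and int(sizes[cid]) > min_size
    ]
    return sorted(chosen, key=lambda cid: -abs(labels[cid].effect))
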