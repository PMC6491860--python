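"""Agglomerative clustering of per-person item-RT profiles.

Persons are points in I-dimensional RT space (raw seconds; a log-RT
option exists behind a flag).  Clustering uses Euclidean distance with
Ward linkage under the Ward.D2 height convention, in which the merge
height of two singletons equals their Euclidean distance.  The number
of clusters is selected automatically at the elbow of the merge-height
curve, operationalized as the maximum second difference of height
versus cluster count; cluster profiles report per-item mean RTs, task
time/score summaries, accuracy and covariate composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .data_model import TaskDataset, five_number, register_result

__all__ = [
    "LinkageTree",
    "ElbowSelection",
    "ClusterProfile",
    "ClusterResult",
    "ward_linkage",
    "elbow_select",
    "cut_tree",
    "profile_clusters",
    "run_clustering",
]


@dataclass
class LinkageTree:
    """Agglomerative merge sequence in scipy linkage-matrix form.

    ``merges`` has one row per merge: (cluster a, cluster b, height,
    merged size); with Ward linkage the heights are non-decreasing.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage matrix must have (n_leaves - 1) x 4 entries")

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def height_at(self, k: int) -> float:
        """Height of the merge that reduces k clusters to k - 1."""
        if not 2 <= k <= self.n_leaves:
            raise ValueError(f"k={k} outside [2, {self.n_leaves}]")
        return float(self.merges[self.n_leaves - k, 2])


def ward_linkage(rt_matrix: np.ndarray, log_rt: bool = False) -> LinkageTree:
    """Ward-linkage agglomeration of RT row vectors (Euclidean distance).

    ``log_rt=True`` clusters log-seconds instead of raw seconds.
    """
    X = np.asarray(rt_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 persons")
    if not np.all(np.isfinite(X)):
        raise ValueError("RT matrix contains non-finite entries")
    if log_rt:
        if np.any(X <= 0):
            raise ValueError("log-RT clustering requires positive RTs")
        X = np.log(X)
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(merges=Z, n_leaves=X.shape[0])


@dataclass
class ElbowSelection:
    """Outcome of elbow-based cluster-count selection.

    ``k`` is the selected count; ``heights`` maps each candidate K to
    the height at which K clusters merge into K - 1; ``curvature`` holds
    the second differences the rule maximized.  ``no_clear_elbow`` marks
    a flat height decay, in which case the smallest admissible K is
    returned with a warning.
    """

    k: int
    heights: dict[int, float]
    curvature: dict[int, float]
    no_clear_elbow: bool


def elbow_select(tree: LinkageTree, k_max: int = 10) -> ElbowSelection:
    """Pick the cluster count at the elbow of the merge-height curve.

    Considers candidate counts K = 2 .. k_max - 1 and maximizes the
    second difference h_K - 2 h_{K+1} + h_{K+2} of the height-versus-K
    curve (ties broken toward smaller K).  When the curve is flat (zero
    curvature everywhere, relative to its own scale) the smallest
    admissible K is returned with a "no clear elbow" warning.
    """
    if tree.n_leaves <= k_max + 1:
        raise ValueError(f"need more than k_max+1={k_max + 1} leaves")
    if k_max < 3:
        raise ValueError("k_max must be at least 3")
    ks = range(2, k_max + 2)
    heights = {k: tree.height_at(k) for k in ks}
    curvature = {
        k: heights[k] - 2.0 * heights[k + 1] + heights[k + 2]
        for k in range(2, k_max)
    }
    scale = max(abs(h) for h in heights.values()) or 1.0
    best_k = min(curvature, key=lambda k: (-curvature[k], k))
    flat = max(curvature.values()) <= 1e-9 * scale
    if flat:
        best_k = 2
        warnings.warn(
            "no clear elbow: merge-height curve has no positive curvature; "
            "returning the smallest admissible cluster count",
            UserWarning,
            stacklevel=2,
        )
    return ElbowSelection(
        k=best_k, heights=heights, curvature=curvature, no_clear_elbow=flat
    )


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels of the k-cluster partition, 1 = largest cluster.

    Labels are 1-based and ordered by cluster size descending (ties by
    first appearance).
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k={k} outside [1, {tree.n_leaves}]")
    raw = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts(sort=False)
    order = sizes.sort_values(ascending=False, kind="stable").index
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[r] for r in raw], dtype=int)


@dataclass
class ClusterProfile:
    """Descriptive profile of one cluster.

    ``score_ci`` is the normal-approximation 95% interval for the mean
    task score (mean +/- 1.96 sd/sqrt(n)); undefined (None) for a
    singleton cluster.
    """

    label: int
    size: int
    mean_rt: np.ndarray
    task_time_fivenum: dict[str, float]
    mean_task_score: float
    score_ci: tuple[float, float] | None
    item_prop_correct: np.ndarray
    covariates: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "size": self.size,
            "mean_rt": self.mean_rt.tolist(),
            "task_time_fivenum": self.task_time_fivenum,
            "mean_task_score": self.mean_task_score,
            "score_ci": list(self.score_ci) if self.score_ci else None,
            "item_prop_correct": self.item_prop_correct.tolist(),
            "covariates": self.covariates,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ClusterProfile":
        return cls(
            label=int(d["label"]),
            size=int(d["size"]),
            mean_rt=np.asarray(d["mean_rt"], dtype=float),
            task_time_fivenum=dict(d["task_time_fivenum"]),
            mean_task_score=float(d["mean_task_score"]),
            score_ci=tuple(d["score_ci"]) if d["score_ci"] else None,
            item_prop_correct=np.asarray(d["item_prop_correct"], dtype=float),
            covariates=dict(d["covariates"]),
        )


def profile_clusters(
    dataset: TaskDataset, labels: np.ndarray
) -> list[ClusterProfile]:
    """Per-cluster timing, accuracy and covariate composition."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (dataset.J,):
        raise ValueError("labels must have one entry per person")
    profiles = []
    for lab in sorted(np.unique(labels)):
        mask = labels == lab
        n = int(mask.sum())
        scores = dataset.task_score[mask].astype(float)
        mean_score = float(scores.mean())
        if n > 1:
            half = 1.96 * scores.std(ddof=1) / np.sqrt(n)
            ci = (mean_score - half, mean_score + half)
        else:
            ci = None
        cov_summary: dict[str, Any] = {}
        if dataset.covariates is not None:
            sub = dataset.covariates[mask]
            for col in sub.columns:
                if isinstance(sub[col].dtype, pd.CategoricalDtype):
                    cov_summary[col] = {
                        str(k): int(v) for k, v in sub[col].value_counts().items()
                    }
                else:
                    cov_summary[col] = {
                        "mean": float(sub[col].mean()),
                        "sd": float(sub[col].std(ddof=1)) if n > 1 else 0.0,
                    }
        profiles.append(
            ClusterProfile(
                label=int(lab),
                size=n,
                mean_rt=dataset.T[mask].mean(axis=0),
                task_time_fivenum=five_number(dataset.task_time[mask]),
                mean_task_score=mean_score,
                score_ci=ci,
                item_prop_correct=dataset.Y[mask].mean(axis=0),
                covariates=cov_summary,
            )
        )
    return profiles


@register_result
@dataclass
class ClusterResult:
    """Labels, selected K, linkage table and per-cluster profiles."""

    labels: np.ndarray
    k: int
    no_clear_elbow: bool
    heights: dict[int, float]
    profiles: list[ClusterProfile] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "labels": np.asarray(self.labels).tolist(),
            "k": self.k,
            "no_clear_elbow": self.no_clear_elbow,
            "heights": {str(k): v for k, v in self.heights.items()},
            "profiles": [p.to_dict() for p in self.profiles],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ClusterResult":
        return cls(
            labels=np.asarray(d["labels"], dtype=int),
            k=int(d["k"]),
            no_clear_elbow=bool(d["no_clear_elbow"]),
            heights={int(k): float(v) for k, v in d["heights"].items()},
            profiles=[ClusterProfile.from_dict(p) for p in d["profiles"]],
        )


def run_clustering(
    dataset: TaskDataset, k_max: int = 10, log_rt: bool = False, k: int | None = None
) -> ClusterResult:
    """Full clustering stage: linkage, elbow selection, cut, profiles."""
    tree = ward_linkage(dataset.T, log_rt=log_rt)
    if k is None:
        sel = elbow_select(tree, k_max=k_max)
        k_use, flat, heights = sel.k, sel.no_clear_elbow, sel.heights
    else:
        k_use, flat = k, False
        heights = {kk: tree.height_at(kk) for kk in range(2, min(k_max, tree.n_leaves) + 1)}
    labels = cut_tree(tree, k_use)
    return ClusterResult(
        labels=labels,
        k=k_use,
        no_clear_elbow=flat,
        heights=heights,
        profiles=profile_clusters(dataset, labels),
    )
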