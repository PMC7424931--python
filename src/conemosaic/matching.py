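"""Correspondence between cone identifications from different annotators.

Two annotators (human graders or an automated detector) click near, but not
exactly on, the same cone centers.  Deciding which selections refer to the
same cone uses an adaptive distance threshold derived from the pooled
("master") coordinate list of all annotators for the ROI: the mean
nearest-coordinate distance plus two sample standard deviations.  Pairs of
selections closer than the threshold are candidate matches; conflicts are
resolved by preferring the closer pair, implemented as a single global
ascending-distance greedy pass, which is deterministic and symmetric in the
two sets.

For more than two annotators, selections are clustered by the same greedy
ascending-distance agglomeration subject to the constraint that a cluster
contains at most one selection per annotator.  Confusion counts (true/false
positives, false negatives) then fall out of either representation, and the
bookkeeping identities

    n_comparison   = n_tp + n_fp
    n_ground_truth = n_tp + n_fn

hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import ConePoints

__all__ = [
    "ThresholdStats",
    "PairMatch",
    "ClusterSet",
    "ConfusionCounts",
    "match_threshold",
    "match_pairwise",
    "cluster_multigrader",
    "confusion_from_match",
    "confusion_from_clusters",
]


class InsufficientPointsError(ValueError):
    """Fewer points than the operation's minimum."""


@dataclass(frozen=True)
class ThresholdStats:
    """Nearest-coordinate statistics of a master list and the derived
    matching threshold (mean NN distance + 2 × sample SD), all in µm."""

    mean_nn_um: float
    sd_nn_um: float
    threshold_um: float

    def __post_init__(self) -> None:
        if self.mean_nn_um < 0 or self.sd_nn_um < 0:
            raise ValueError("NN statistics must be non-negative")


@dataclass
class PairMatch:
    """One-to-one correspondence between a ground-truth and a comparison set.

    ``matched_pairs`` holds (gt index, comp index, distance µm) triples;
    every index appears at most once and every pair distance is within the
    threshold.  Unmatched indices of either side are listed separately.
    """

    threshold: ThresholdStats
    matched_pairs: list[tuple[int, int, float]]
    unmatched_gt: list[int]
    unmatched_comp: list[int]
    n_gt: int
    n_comp: int


@dataclass
class ClusterSet:
    """Multi-annotator clusters of cone selections.

    Each cluster maps annotator label -> point index within that
    annotator's set; at most one selection per annotator per cluster, and
    every selection of every annotator belongs to exactly one cluster
    (singletons allowed).
    """

    graders: list[str]
    clusters: list[dict[str, int]]
    threshold: ThresholdStats


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive and false negative counts for one ordered
    (ground truth, comparison) annotator pair."""

    n_tp: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_gt(self) -> int:
        return self.n_tp + self.n_fn

    @property
    def n_comp(self) -> int:
        return self.n_tp + self.n_fp


def match_threshold(master: np.ndarray) -> ThresholdStats:
    """Adaptive matching threshold from a pooled master coordinate list.

    For every point the distance to its nearest *other* point in the master
    list (self excluded, all annotators pooled) is computed; the threshold
    is the mean of these distances plus twice their sample (n−1) standard
    deviation.

    Parameters
    ----------
    master : (n, 2) array, n ≥ 2
        Pooled coordinates in µm.
    """
    master = np.asarray(master, dtype=float).reshape(-1, 2)
    if len(master) < 2:
        raise InsufficientPointsError(
            f"master list needs ≥ 2 points, got {len(master)}"
        )
    tree = cKDTree(master)
    # k=2: first hit is the point itself at distance 0 (coincident points
    # still yield a valid 0 distance via the second hit).
    dists, _ = tree.query(master, k=2)
    nn = dists[:, 1]
    mean = float(np.mean(nn))
    sd = float(np.std(nn, ddof=1))
    return ThresholdStats(mean_nn_um=mean, sd_nn_um=sd, threshold_um=mean + 2.0 * sd)


def _candidate_pairs(a: np.ndarray, b: np.ndarray, threshold: float):
    """All (i, j, d) with ``d = |a_i - b_j| ≤ threshold``, sorted by
    (distance, i, j) — the deterministic greedy order."""
    if len(a) == 0 or len(b) == 0:
        return []
    tree_b = cKDTree(b)
    pairs = []
    for i, neighbors in enumerate(cKDTree(a).query_ball_tree(tree_b, threshold)):
        for j in neighbors:
            d = float(np.hypot(*(a[i] - b[j])))
            pairs.append((d, i, j))
    pairs.sort()
    return [(i, j, d) for d, i, j in pairs]


def match_pairwise(
    gt: ConePoints, comp: ConePoints, threshold: ThresholdStats
) -> PairMatch:
    """One-to-one match of a comparison set against a ground-truth set.

    Candidate pairs are all cross-set pairs within the threshold distance
    (inclusive).  They are accepted greedily in ascending distance order,
    skipping pairs whose endpoint is already matched — the "closer cone
    wins" rule, made globally consistent and direction-symmetric.  Exact
    distance ties break on (lower gt index, lower comp index).
    """
    if gt.roi is not comp.roi and (
        gt.roi.subject_id != comp.roi.subject_id or gt.roi.roi_id != comp.roi.roi_id
    ):
        raise ValueError(
            f"sets belong to different ROIs: {gt.roi.roi_id!r} vs {comp.roi.roi_id!r}"
        )
    if threshold.threshold_um < 0:
        raise ValueError("threshold must be non-negative")

    used_gt: set[int] = set()
    used_comp: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    for i, j, d in _candidate_pairs(gt.coords, comp.coords, threshold.threshold_um):
        if i in used_gt or j in used_comp:
            continue
        used_gt.add(i)
        used_comp.add(j)
        matched.append((i, j, d))

    return PairMatch(
        threshold=threshold,
        matched_pairs=matched,
        unmatched_gt=[i for i in range(len(gt)) if i not in used_gt],
        unmatched_comp=[j for j in range(len(comp)) if j not in used_comp],
        n_gt=len(gt),
        n_comp=len(comp),
    )


def cluster_multigrader(
    sets: list[ConePoints], threshold: ThresholdStats | None = None
) -> ClusterSet:
    """Cluster the selections of ≥ 2 annotators into per-cone groups.

    The threshold is computed from the combined master list of all
    annotators (unless supplied).  Clusters are grown by greedy
    agglomeration over cross-annotator candidate pairs in ascending
    distance order: two clusters merge only when their annotator sets are
    disjoint, so a cluster never holds two selections by the same
    annotator.  With two annotators this reduces exactly to
    :func:`match_pairwise`.  Deterministic for a fixed input order.
    """
    if len(sets) < 2:
        raise ValueError(f"need ≥ 2 annotators, got {len(sets)}")
    labels = [s.annotator for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate annotator labels: {labels}")

    all_pts = [s.coords for s in sets if len(s)]
    master = np.vstack(all_pts) if all_pts else np.empty((0, 2))
    if threshold is None:
        threshold = match_threshold(master)

    # Flat indexing over the pooled points: (annotator ordinal, local index).
    owner: list[tuple[int, int]] = []
    for a, s in enumerate(sets):
        owner.extend((a, k) for k in range(len(s)))
    flat = (
        np.vstack([s.coords for s in sets if len(s)])
        if owner
        else np.empty((0, 2))
    )

    parent = list(range(len(owner)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: list[set[int]] = [{find(i)} for i in range(len(owner))]
    annset: list[set[int]] = [{owner[i][0]} for i in range(len(owner))]

    pairs = []
    for i, j, d in _candidate_pairs(flat, flat, threshold.threshold_um):
        if i < j and owner[i][0] != owner[j][0]:
            pairs.append((d, i, j))
    pairs.sort()
    for _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if annset[ri] & annset[rj]:
            continue  # would put two selections of one annotator together
        parent[rj] = ri
        members[ri] |= members[rj]
        annset[ri] |= annset[rj]

    roots = sorted({find(i) for i in range(len(owner))})
    clusters = []
    for r in roots:
        group = sorted(members[r])
        clusters.append({labels[owner[i][0]]: owner[i][1] for i in group})
    return ClusterSet(graders=labels, clusters=clusters, threshold=threshold)


def confusion_from_match(match: PairMatch) -> ConfusionCounts:
    """Confusion counts of a pairwise match: matched pairs are true
    positives, unmatched ground-truth points false negatives, unmatched
    comparison points false positives."""
    return ConfusionCounts(
        n_tp=len(match.matched_pairs),
        n_fp=len(match.unmatched_comp),
        n_fn=len(match.unmatched_gt),
    )


def confusion_from_clusters(
    clusters: ClusterSet, ground_truth_annotator: str, comparison_annotator: str
) -> ConfusionCounts:
    """Confusion counts for one ordered annotator pair read off a cluster
    set: clusters holding both annotators are true positives; ground truth
    only, false negatives; comparison only, false positives.  Clusters
    containing neither annotator are ignored."""
    for lab in (ground_truth_annotator, comparison_annotator):
        if lab not in clusters.graders:
            raise ValueError(f"unknown annotator {lab!r}; have {clusters.graders}")
    tp = fp = fn = 0
    for c in clusters.clusters:
        has_gt = ground_truth_annotator in c
        has_comp = comparison_annotator in c
        if has_gt and has_comp:
            tp += 1
        elif has_gt:
            fn += 1
        elif has_comp:
            fp += 1
    return ConfusionCounts(n_tp=tp, n_fp=fp, n_fn=fn)
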