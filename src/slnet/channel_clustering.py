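"""Channel clustering on nodal-efficiency profiles and cross-task matching.

For each band and task, the 19 channels are described by their mean nodal
efficiency on each stimulus (averaged over subjects), giving a 19 x
n_stimuli feature table. K-means groups channels with similar activation
profiles; the clusters of the six main tasks are then matched into
cross-task groups by Jaccard similarity of their member sets, and channels
that consistently belong to a group's cluster for one task type
(equation-solving vs programming) but not the other are reported as
*differentiating elements*, annotated with their Brodmann areas.

Rows are clustered unscaled (the efficiencies already share a scale); a
z-score option exists for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .recordings import MONTAGE, MontageEntry

__all__ = [
    "ChannelFeatureTable",
    "ClusterAssignment",
    "ClusterGroupMatch",
    "build_feature_table",
    "choose_k",
    "cluster_channels",
    "match_cluster_groups",
    "differentiating_elements",
    "E_TASKS",
    "P_TASKS",
]

E_TASKS = ("ES", "EM", "EC")
P_TASKS = ("PS", "PM", "PC")


@dataclass
class ChannelFeatureTable:
    """Channels x stimuli mean nodal efficiencies for one band and task."""

    values: np.ndarray
    band: str | None = None
    task: str | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature table must be channels x stimuli")
        if np.any(~np.isfinite(v)):
            raise ValueError("feature table contains missing entries")
        self.values = v
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"Ch{i + 1:02d}" for i in range(v.shape[0])
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterAssignment:
    """K-means labels (1..K) per channel, canonicalized by mean level."""

    labels: np.ndarray
    k: int
    inertia: float
    seed: int | None = None
    task: str | None = None

    def members(self, cluster_id: int) -> set[int]:
        """1-based channel indices belonging to ``cluster_id``."""
        return set((np.nonzero(self.labels == cluster_id)[0] + 1).tolist())


@dataclass
class ClusterGroupMatch:
    """One cross-task group of matched clusters."""

    group_id: int
    cluster_by_task: dict[str, int]
    members_by_task: dict[str, set[int]]
    common_channels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        sets = list(self.members_by_task.values())
        self.common_channels = set.intersection(*sets) if sets else set()


def build_feature_table(
    el: np.ndarray,
    band: str | None = None,
    task: str | None = None,
    channel_labels: tuple[str, ...] = (),
) -> ChannelFeatureTable:
    """Average per-subject nodal efficiencies into a channels x stimuli table.

    ``el`` has shape (n_subjects, n_stimuli, n_channels): the nodal
    efficiency of every channel on every stimulus epoch. Entry (ch, s) of
    the result is the mean over subjects of El_ch on stimulus s.
    """
    el = np.asarray(el, dtype=float)
    if el.ndim != 3:
        raise ValueError("el must be subjects x stimuli x channels")
    if np.any(np.all(~np.isfinite(el), axis=0)):
        raise ValueError("a stimulus is missing for every subject")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(el, axis=0)  # stimuli x channels
    return ChannelFeatureTable(mean.T, band=band, task=task,
                               channel_labels=channel_labels)


def choose_k(
    table: ChannelFeatureTable,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    seed: int | None = None,
) -> tuple[dict[int, float], np.ndarray]:
    """Mean silhouette per candidate K plus an agglomerative linkage.

    Silhouettes use Euclidean distance on the K-means labels; the returned
    Ward linkage matrix supports a dendrogram of the same rows.
    """
    x = table.values
    n = x.shape[0]
    if np.allclose(x, x[0]):
        raise ValueError("all rows identical: clustering degenerate")
    scores: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"K={k} outside 2..{n - 1}")
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
        if len(set(labels)) < 2:
            scores[k] = float("nan")
        else:
            scores[k] = float(silhouette_score(x, labels, metric="euclidean"))
    return scores, linkage(x, method="ward")


def cluster_channels(
    table: ChannelFeatureTable,
    k: int = 3,
    seed: int | None = None,
    standardize: bool = False,
) -> ClusterAssignment:
    """K-means over channel rows with canonical labels.

    Multiple restarts (n_init=10) guard against poor initializations.
    Labels are renumbered 1..K by descending cluster mean efficiency so that
    label identity is stable across runs that find the same partition.
    """
    x = table.values
    if not 2 <= k <= x.shape[0] - 1:
        raise ValueError(f"K={k} invalid for {x.shape[0]} channels")
    if standardize:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    raw = km.labels_
    means = np.array([table.values[raw == c].mean() for c in range(k)])
    order = np.argsort(-means, kind="stable")  # canonical id 1 = highest level
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterAssignment(labels=relabel[raw], k=k,
                             inertia=float(km.inertia_), seed=seed,
                             task=table.task)


def _jaccard(a: set[int], b: set[int]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def match_cluster_groups(
    assignments: Mapping[str, ClusterAssignment],
    anchor_task: str | None = None,
) -> list[ClusterGroupMatch]:
    """Match clusters across tasks into K cross-task groups.

    Anchored on the first task (or ``anchor_task``): for every other task, a
    bijection between its clusters and the anchor's is built greedily by
    maximal Jaccard similarity of member sets, ties resolved toward the
    lower cluster id. Group g collects the clusters matched to anchor
    cluster g; ``common_channels`` are the channels present in every task's
    matched cluster.
    """
    tasks = list(assignments)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks to match")
    ks = {a.k for a in assignments.values()}
    if len(ks) != 1:
        raise ValueError("all tasks must be clustered at the same K")
    k = ks.pop()
    anchor = anchor_task if anchor_task is not None else tasks[0]
    if anchor not in assignments:
        raise ValueError(f"anchor task {anchor!r} not in assignments")

    anchor_members = {c: assignments[anchor].members(c) for c in range(1, k + 1)}
    cluster_by_task: dict[int, dict[str, int]] = {g: {anchor: g} for g in range(1, k + 1)}
    for task in tasks:
        if task == anchor:
            continue
        members = {c: assignments[task].members(c) for c in range(1, k + 1)}
        free_anchor = set(anchor_members)
        free_task = set(members)
        while free_anchor:
            best = max(
                ((g, c) for g in sorted(free_anchor) for c in sorted(free_task)),
                key=lambda gc: (_jaccard(anchor_members[gc[0]], members[gc[1]]),
                                -gc[0], -gc[1]),
            )
            g, c = best
            cluster_by_task[g][task] = c
            free_anchor.remove(g)
            free_task.remove(c)

    groups = []
    for g in range(1, k + 1):
        members_by_task = {
            t: assignments[t].members(cluster_by_task[g][t]) for t in tasks
        }
        groups.append(
            ClusterGroupMatch(
                group_id=g,
                cluster_by_task=cluster_by_task[g],
                members_by_task=members_by_task,
            )
        )
    return groups


def differentiating_elements(
    group: ClusterGroupMatch,
    e_tasks: Sequence[str] = E_TASKS,
    p_tasks: Sequence[str] = P_TASKS,
    within_min: int = 2,
    cross_max: int = 1,
) -> dict[str, dict[int, MontageEntry]]:
    """Channels that separate the two task types within one cluster group.

    A channel is differentiating for type P when it belongs to the group's
    matched cluster in at least ``within_min`` of the P tasks and at most
    ``cross_max`` of the E tasks (and symmetrically for E). Returns
    ``{"E": {...}, "P": {...}}`` mapping 1-based channel indices to their
    montage entry (electrode name and Brodmann annotation).
    """
    def counts(tasks: Sequence[str]) -> dict[int, int]:
        c: dict[int, int] = {}
        for t in tasks:
            if t not in group.members_by_task:
                raise ValueError(f"task {t!r} missing from the group")
            for ch in group.members_by_task[t]:
                c[ch] = c.get(ch, 0) + 1
        return c

    e_counts = counts(e_tasks)
    p_counts = counts(p_tasks)
    out: dict[str, dict[int, MontageEntry]] = {"E": {}, "P": {}}
    all_channels = set(e_counts) | set(p_counts)
    for ch in sorted(all_channels):
        in_e = e_counts.get(ch, 0)
        in_p = p_counts.get(ch, 0)
        entry = MONTAGE[ch - 1] if 1 <= ch <= len(MONTAGE) else None
        if in_p >= within_min and in_e <= cross_max:
            out["P"][ch] = entry
        if in_e >= within_min and in_p <= cross_max:
            out["E"][ch] = entry
    return out
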