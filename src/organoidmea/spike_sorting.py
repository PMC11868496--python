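"""Waveform clustering into putative units and spikeform similarity.

Each channel's spike waveforms are centred, projected onto their top two
principal components and partitioned with k-means into 2 or 3 clusters
(the number either fixed or chosen by silhouette score).  Cluster mean
waveforms ("mean spikeforms") summarise each putative unit; Pearson
correlation between spikeforms quantifies whether two recordings (e.g.
before and after tilting an electrode) saw the same unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._types import Waveform

__all__ = [
    "SortingParams",
    "UnitCluster",
    "sort_channel",
    "spikeform_similarity",
    "cluster_set_similarity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SortingParams:
    """Feature-reduction and clustering parameters.

    Waveforms are reduced to ``n_components`` (two) principal components.
    ``k_choices`` lists the admissible cluster counts; with
    ``k_selection="silhouette"`` the count with the best silhouette score
    is used, with ``"fixed"`` the first entry of ``k_choices`` is forced.
    """

    n_components: int = 2
    k_choices: tuple[int, ...] = (2, 3)
    k_selection: str = "silhouette"
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_components != 2:
            raise ValueError("feature space is two-dimensional")
        if not set(self.k_choices) <= {2, 3}:
            raise ValueError("cluster counts are restricted to 2 or 3")
        if self.k_selection not in ("fixed", "silhouette"):
            raise ValueError(f"unknown k_selection {self.k_selection!r}")


@dataclass
class UnitCluster:
    """One putative unit on one channel."""

    channel: int
    label: int
    member_indices: np.ndarray
    mean_waveform: np.ndarray


def _cluster_list(
    channel: int, labels: np.ndarray, X: np.ndarray
) -> list[UnitCluster]:
    clusters = []
    for new_label, old in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == old)
        clusters.append(
            UnitCluster(
                channel=channel,
                label=new_label,
                member_indices=idx,
                mean_waveform=X[idx].mean(axis=0),
            )
        )
    return clusters


def sort_channel(
    waveforms: list[Waveform], p: SortingParams = SortingParams()
) -> list[UnitCluster]:
    """Cluster one channel's waveforms into putative units.

    Fewer than two waveforms (or fewer distinct waveforms than clusters)
    yield a single trivial cluster.  Deterministic given ``p.seed``.
    """
    if not waveforms:
        return []
    channel = waveforms[0].channel
    if any(w.channel != channel for w in waveforms):
        raise ValueError("sort_channel expects waveforms from a single channel")
    X = np.vstack([w.samples for w in waveforms])
    n = X.shape[0]
    n_distinct = np.unique(X, axis=0).shape[0]
    k_max = max(p.k_choices)
    if n < 2 or n_distinct < 2:
        return _cluster_list(channel, np.zeros(n, dtype=int), X)

    n_comp = min(p.n_components, n, X.shape[1])
    feats = PCA(n_components=n_comp, random_state=p.seed).fit_transform(
        X - X.mean(axis=0)
    )

    candidates = [k for k in sorted(p.k_choices) if k <= min(n, n_distinct)]
    if not candidates:
        return _cluster_list(channel, np.zeros(n, dtype=int), X)
    if p.k_selection == "fixed":
        candidates = candidates[:1]

    best_labels, best_score = None, -np.inf
    for k in candidates:
        km = KMeans(
            n_clusters=k, n_init=p.n_restarts, random_state=p.seed
        ).fit(feats)
        if len(candidates) == 1:
            best_labels = km.labels_
            break
        try:
            score = silhouette_score(feats, km.labels_)
        except ValueError:  # degenerate: a single effective cluster
            score = -np.inf
        if score > best_score:
            best_score, best_labels = score, km.labels_
    clusters = _cluster_list(channel, best_labels, X)
    logger.debug(
        "channel %d: %d waveforms -> %d clusters (k_max %d)",
        channel, n, len(clusters), k_max,
    )
    return clusters


def spikeform_similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """Pearson correlation between two spikeform vectors.

    Raises
    ------
    ValueError
        On length mismatch or zero-variance input, where the correlation
        is undefined.
    """
    w1 = np.asarray(w1, dtype=float).ravel()
    w2 = np.asarray(w2, dtype=float).ravel()
    if w1.size != w2.size:
        raise ValueError("spikeforms must have equal length")
    if w1.size < 2 or np.std(w1) == 0 or np.std(w2) == 0:
        raise ValueError("spikeform correlation undefined for constant input")
    return float(np.corrcoef(w1, w2)[0, 1])


def cluster_set_similarity(
    means_a: list[np.ndarray], means_b: list[np.ndarray]
) -> float:
    """Similarity between two sets of mean spikeforms (e.g. pre vs post tilt).

    Pairs are matched greedily by best Pearson r (each mean used at most
    once); the returned value is the mean r over matched pairs.
    """
    if not means_a or not means_b:
        raise ValueError("both cluster sets must be non-empty")
    r = np.full((len(means_a), len(means_b)), -np.inf)
    for i, a in enumerate(means_a):
        for j, b in enumerate(means_b):
            r[i, j] = spikeform_similarity(a, b)
    rs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _ in range(min(len(means_a), len(means_b))):
        masked = r.copy()
        masked[list(used_a), :] = -np.inf
        masked[:, list(used_b)] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        rs.append(r[i, j])
        used_a.add(int(i))
        used_b.add(int(j))
    return float(np.mean(rs))
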