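"""Classification of dentate spikes into DS1 and DS2.

Per-event CSD maps (fissure-to-hilus window, DS-band filtered LFP) are
normalized to unit peak magnitude, embedded in 2-D with PCA, clustered with
K-means or DBSCAN, and the two clusters are auto-labeled by the depth of
their maximal current sink at the event-center time bin: the sink closer to
the fissure is DS1, the one closer to the granule cell layer is DS2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core import ConfigurationError
from .csd import CSDStack

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationResult",
    "normalize_profiles",
    "pca_embed",
    "cluster_events",
    "auto_label_clusters",
    "swap_labels",
    "classify_ds",
]

UNDEFINED = "undefined"


@dataclass
class ClassificationResult:
    event_ids: np.ndarray          # events that entered clustering
    coords: np.ndarray             # (n_events, 2) PCA coordinates
    labels: np.ndarray             # per event: "1" | "2" | "undefined"
    sink_channel: dict             # label -> analysis channel of max sink
    counts: dict                   # label -> event count
    cluster_mean_csd: dict         # label -> channels x time map
    cluster_mean_lfp: dict
    explained_variance: np.ndarray
    provenance: dict = field(default_factory=dict)
    low_confidence: bool = False


def normalize_profiles(stack: CSDStack) -> tuple[np.ndarray, np.ndarray]:
    """Flatten each event's CSD map and scale by its own peak magnitude.

    Returns (features, kept_event_ids); all-zero maps are excluded with a
    warning and later receive the undefined label.
    """
    if stack.n_events < 2:
        raise ConfigurationError("need at least 2 events to classify")
    flat = stack.csd.reshape(stack.n_events, -1)
    peak = np.abs(flat).max(axis=1)
    keep = peak > 0
    if not keep.all():
        logger.warning("%d all-zero CSD maps excluded from clustering",
                       int((~keep).sum()))
    flat = flat[keep] / peak[keep, None]
    return flat, stack.event_ids[keep]


def pca_embed(features: np.ndarray, n_components: int = 2,
              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered projection onto the top principal axes.

    Returns (coordinates, explained-variance fractions). Deterministic up
    to axis sign. Rank-deficient input (all events identical) yields zero
    coordinates with a warning.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ConfigurationError("PCA needs at least 2 events and 2 features")
    if np.allclose(features, features[0]):
        logger.warning("all events identical; PCA coordinates are zero")
        return np.zeros((features.shape[0], n_components)), np.zeros(n_components)
    n_components = min(n_components, *features.shape)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(features)
    return coords, pca.explained_variance_ratio_


def cluster_events(coords: np.ndarray, algorithm: str = "kmeans",
                   k: int = 2, epsilon: float = 0.5, min_samples: int = 5,
                   seed: int = 0) -> np.ndarray:
    """Cluster PCA coordinates; DBSCAN noise points are labeled -1.

    A silhouette below 0.2 (poorly separated split) logs a warning but
    still returns the partition.
    """
    coords = np.asarray(coords, dtype=float)
    if algorithm == "kmeans":
        if k > len(coords):
            raise ConfigurationError(f"k={k} exceeds {len(coords)} events")
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    elif algorithm == "dbscan":
        # epsilon is in normalized PC units: coordinates are divided by
        # their overall standard deviation before density clustering
        scale = coords.std()
        scaled = coords / scale if scale > 0 else coords
        labels = DBSCAN(eps=epsilon, min_samples=min_samples).fit_predict(scaled)
    else:
        raise ConfigurationError(f"unknown clustering algorithm {algorithm!r}")
    labeled = labels[labels >= 0]
    if len(np.unique(labeled)) >= 2:
        try:
            sil = silhouette_score(coords[labels >= 0], labeled)
            if sil < 0.2:
                logger.warning("weak cluster separation (silhouette %.2f)", sil)
        except ValueError:
            pass
    return labels


def _sink_channel(mean_csd: np.ndarray, center_bin: int) -> int:
    """Index (within the window) of the maximal sink at the center bin."""
    return int(np.argmin(mean_csd[:, center_bin]))


def auto_label_clusters(raw_labels: np.ndarray, stack: CSDStack,
                        kept_event_ids: np.ndarray,
                        theta_channel: int, ds_channel: int,
                        provenance: dict | None = None) -> ClassificationResult:
    """Assign DS1/DS2 by sink depth.

    For each of the two clusters, the sink channel is the argmin of the
    cluster-mean CSD at the event-center time bin. The cluster whose sink
    lies nearer (in analysis-channel index) to the theta/fissure channel is
    DS1; the other, nearer the granule cell layer, is DS2. Ties go to the
    shallower sink as DS1. DBSCAN noise points stay undefined.
    """
    raw_labels = np.asarray(raw_labels)
    cluster_ids = [c for c in np.unique(raw_labels) if c >= 0]
    if len(cluster_ids) != 2:
        raise ConfigurationError(
            f"auto-labeling requires exactly 2 clusters, got {len(cluster_ids)}")
    id_to_pos = {int(e): i for i, e in enumerate(stack.event_ids)}
    pos = np.array([id_to_pos[int(e)] for e in kept_event_ids])
    cb = stack.center_bin
    sink_win, mean_csd, mean_lfp = {}, {}, {}
    for c in cluster_ids:
        sel = pos[raw_labels == c]
        mean_csd[c] = stack.csd[sel].mean(axis=0)
        mean_lfp[c] = stack.lfp[sel].mean(axis=0)
        sink_win[c] = _sink_channel(mean_csd[c], cb)

    low_conf = False
    a, b = cluster_ids
    if sink_win[a] == sink_win[b]:
        # degenerate: same primary sink; fall back to the second-deepest sink
        low_conf = True
        logger.warning("clusters share a sink channel; using secondary sink")
        for c in cluster_ids:
            sink_win[c] = int(np.argsort(mean_csd[c][:, cb])[1])

    # distance to the fissure end of the window, in analysis-channel units
    chans = stack.channels
    def dist_to_fissure(c):
        return abs(int(chans[sink_win[c]]) - theta_channel)
    def dist_to_hilus(c):
        return abs(int(chans[sink_win[c]]) - ds_channel)

    if dist_to_fissure(a) == dist_to_fissure(b):
        # tie: shallower sink (smaller analysis index) is DS1
        ds1 = a if chans[sink_win[a]] < chans[sink_win[b]] else b
    else:
        ds1 = a if dist_to_fissure(a) < dist_to_fissure(b) else b
    ds2 = b if ds1 == a else a

    label_map = {ds1: "1", ds2: "2"}
    labels = np.array([label_map.get(int(l), UNDEFINED) for l in raw_labels])
    result = ClassificationResult(
        event_ids=np.asarray(kept_event_ids),
        coords=np.empty((len(kept_event_ids), 0)),
        labels=labels,
        sink_channel={"1": int(chans[sink_win[ds1]]), "2": int(chans[sink_win[ds2]])},
        counts={
            "1": int((labels == "1").sum()),
            "2": int((labels == "2").sum()),
            UNDEFINED: int((labels == UNDEFINED).sum()),
        },
        cluster_mean_csd={"1": mean_csd[ds1], "2": mean_csd[ds2]},
        cluster_mean_lfp={"1": mean_lfp[ds1], "2": mean_lfp[ds2]},
        explained_variance=np.array([]),
        provenance=dict(provenance or {}),
        low_confidence=low_conf,
    )
    return result


def swap_labels(result: ClassificationResult) -> ClassificationResult:
    """Exchange DS1 and DS2 everywhere (manual override); involution."""
    swap = {"1": "2", "2": "1"}
    labels = np.array([swap.get(l, l) for l in result.labels])
    prov = dict(result.provenance)
    prov["manual_swaps"] = prov.get("manual_swaps", 0) + 1
    return ClassificationResult(
        event_ids=result.event_ids,
        coords=result.coords,
        labels=labels,
        sink_channel={"1": result.sink_channel["2"], "2": result.sink_channel["1"]},
        counts={"1": result.counts["2"], "2": result.counts["1"],
                UNDEFINED: result.counts[UNDEFINED]},
        cluster_mean_csd={"1": result.cluster_mean_csd["2"],
                          "2": result.cluster_mean_csd["1"]},
        cluster_mean_lfp={"1": result.cluster_mean_lfp["2"],
                          "2": result.cluster_mean_lfp["1"]},
        explained_variance=result.explained_variance,
        provenance=prov,
        low_confidence=result.low_confidence,
    )


def classify_ds(stack: CSDStack, theta_channel: int, ds_channel: int,
                algorithm: str = "kmeans", k: int = 2, epsilon: float = 0.5,
                min_samples: int = 5, seed: int = 0) -> ClassificationResult:
    """Full chain: normalize -> PCA -> cluster -> auto-label."""
    features, kept = normalize_profiles(stack)
    coords, evr = pca_embed(features, n_components=2, seed=seed)
    raw = cluster_events(coords, algorithm=algorithm, k=k, epsilon=epsilon,
                         min_samples=min_samples, seed=seed)
    prov = {"algorithm": algorithm, "seed": seed,
            "params": {"k": k} if algorithm == "kmeans"
            else {"epsilon": epsilon, "min_samples": min_samples}}
    result = auto_label_clusters(raw, stack, kept, theta_channel, ds_channel,
                                 provenance=prov)
    result.coords = coords
    result.explained_variance = evr
    # events excluded from clustering (all-zero maps) are undefined
    excluded = set(map(int, stack.event_ids)) - set(map(int, kept))
    if excluded:
        result.counts[UNDEFINED] += len(excluded)
    return result
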