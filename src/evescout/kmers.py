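"""Canonical k-mer composition profiles and two-stage scaffold clustering.

Scaffolds are profiled by canonical pentamer (default) frequencies and
clustered to separate the central "core" cloud of host scaffolds from
satellite clusters of divergent composition. Clustering is two-stage: long
scaffolds (>= ``min_len``, default 33 kb) are clustered on a
variance-preserving linear projection of their profiles; shorter scaffolds
are then assigned to the nearest stage-1 centroid. The core is the cluster
with the greatest summed scaffold length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


@dataclass
class KmerProfile:
    scaffold_id: str
    k: int
    freq: np.ndarray  # canonical k-mer frequencies, sum to 1


@dataclass
class ClusterAssignment:
    scaffold_id: str
    cluster_id: int
    role: str   # "core" | "satellite"
    stage: str  # "primary" | "assigned"
    coords: Tuple[float, float]  # top-2 embedding coordinates, for plotting


@lru_cache(maxsize=8)
def _canonical_map(k: int) -> Tuple[np.ndarray, int]:
    """Map each 2-bit-encoded k-mer code to a canonical index.

    A k-mer and its reverse complement share an index (the lexicographically
    smaller code represents the pair). For odd k there are 4**k / 2 classes.
    """
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))  # complement: A<->T, C<->G in 2-bit
        tmp >>= 2
    canon = np.minimum(codes, rc)
    reps = np.unique(canon)
    index = np.zeros(4 ** k, dtype=np.int64)
    index[reps] = np.arange(len(reps))
    return index[canon], len(reps)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i


def kmer_profile(sequence: str, k: int = 5, scaffold_id: str = "") -> KmerProfile:
    """Canonical k-mer frequency profile over all sliding windows.

    Windows containing a non-ACGT base are skipped. Raises if the sequence is
    shorter than k, or if every window is ambiguous.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} is shorter than k={k}")
    b = _BASE_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n_windows = len(b) - k + 1
    codes = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for i in range(k):
        part = b[i:i + n_windows]
        valid &= part >= 0
        codes = (codes << 2) | np.maximum(part, 0).astype(np.int64)
    if not valid.any():
        raise ValueError("every window contains an ambiguous (non-ACGT) base; "
                         "no valid k-mers to count")
    canon, n_canon = _canonical_map(k)
    counts = np.bincount(canon[codes[valid]], minlength=n_canon)
    return KmerProfile(scaffold_id, k, counts / counts.sum())


def cluster_scaffolds(profiles: Mapping[str, KmerProfile],
                      lengths: Mapping[str, int],
                      min_len: int = 33_000,
                      variance_target: float = 0.9,
                      max_clusters: int = 10,
                      seed: int = 0) -> List[ClusterAssignment]:
    """Two-stage composition clustering with core/satellite labeling.

    Stage 1: scaffolds >= ``min_len`` are projected onto the leading principal
    components explaining >= ``variance_target`` of profile variance and
    clustered with seed-fixed k-means, the cluster count chosen by silhouette
    over 2..``max_clusters``. Stage 2: shorter scaffolds are assigned to the
    nearest stage-1 centroid. Core = cluster with the greatest summed length
    of its stage-1 members (ties: more scaffolds, then lexicographically
    smallest member id). Deterministic given a seed and invariant to input
    order (ids are sorted internally).
    """
    ids = sorted(profiles)
    long_ids = [s for s in ids if lengths[s] >= min_len]
    short_ids = [s for s in ids if lengths[s] < min_len]
    if not long_ids:
        raise ValueError(
            f"no scaffold reaches min_len={min_len}; lower min_len to enable "
            "the first clustering stage")

    if len(long_ids) == 1:
        # a single long scaffold defines the (only, core) cluster
        return ([ClusterAssignment(long_ids[0], 0, "core", "primary", (0.0, 0.0))]
                + [ClusterAssignment(s, 0, "core", "assigned", (0.0, 0.0))
                   for s in short_ids])

    X_long = np.vstack([profiles[s].freq for s in long_ids])
    n_comp = min(len(long_ids), X_long.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    emb_long = pca.fit_transform(X_long)
    if n_comp > 1:
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, variance_target) + 1)
        keep = max(2, min(keep, n_comp))
    else:
        keep = 1
    emb_long = emb_long[:, :keep]

    best = None
    for n_clusters in range(2, min(max_clusters, len(long_ids) - 1) + 1):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        lab = km.fit_predict(emb_long)
        if len(set(lab)) < 2:
            continue
        score = silhouette_score(emb_long, lab)
        if best is None or score > best[0] + 1e-12:
            best = (score, lab, km.cluster_centers_)
    if best is None:  # degenerate: identical profiles or only 2 long scaffolds
        labels = np.zeros(len(long_ids), dtype=int)
        centroids = emb_long.mean(axis=0, keepdims=True)
    else:
        _, labels, centroids = best

    # Core: greatest summed stage-1 length; ties broken by member count then id.
    cluster_ids = sorted(set(labels.tolist()))
    def _core_key(c: int):
        members = [s for s, l in zip(long_ids, labels) if l == c]
        return (-sum(lengths[s] for s in members), -len(members), min(members))
    core_cluster = min(cluster_ids, key=_core_key)

    out: List[ClusterAssignment] = []
    for s, lab, coords in zip(long_ids, labels, emb_long):
        out.append(ClusterAssignment(
            s, int(lab), "core" if lab == core_cluster else "satellite",
            "primary", (float(coords[0]), float(coords[1]) if keep > 1 else 0.0)))
    if short_ids:
        X_short = np.vstack([profiles[s].freq for s in short_ids])
        emb_short = pca.transform(X_short)[:, :keep]
        dists = ((emb_short[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        nearest = dists.argmin(axis=1)
        for s, lab, coords in zip(short_ids, nearest, emb_short):
            out.append(ClusterAssignment(
                s, int(lab), "core" if lab == core_cluster else "satellite",
                "assigned", (float(coords[0]), float(coords[1]) if keep > 1 else 0.0)))
    out.sort(key=lambda a: a.scaffold_id)
    return out
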