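"""Tanimoto similarity, Butina sphere-exclusion clustering, and fold
construction for nested cross-validation.

The Butina clustering here is written from first principles (it is the
splitting primitive the cluster-integrity evaluation depends on): build
neighbour lists at ``similarity >= threshold``, then repeatedly take the
unassigned compound with the most unassigned neighbours as a centroid,
assign it together with those neighbours, and continue until everything
is assigned; compounds without neighbours end up as singletons. Ties on
the neighbour count go to the lowest input index, which makes the
procedure fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curation import ACTIVE, ClassifiedDataset
from .descriptors import Fingerprint

SCHEMES = ("random", "cluster")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a & b| / |a | b| between two bit-sets.

    Defined as 0 (with a warning) when both fingerprints are empty.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"mixed bit universes: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0")
        return 0.0
    return len(a.bits & b.bits) / union


def _bit_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    n_bits = {fp.n_bits for fp in fps}
    if len(n_bits) > 1:
        raise ValueError(f"mixed bit universes in fingerprint list: {sorted(n_bits)}")
    # float64 keeps the 0/1 dot products exact integers, so similarities
    # match scalar set arithmetic bit for bit
    mat = np.zeros((len(fps), n_bits.pop()), dtype=np.float64)
    for i, fp in enumerate(fps):
        mat[i, list(fp.bits)] = 1.0
    return mat


def tanimoto_matrix(
    fps_a: Sequence[Fingerprint], fps_b: Sequence[Fingerprint] | None = None
) -> np.ndarray:
    """All-pairs Tanimoto similarity, vectorized over packed bit rows."""
    A = _bit_matrix(fps_a)
    B = A if fps_b is None else _bit_matrix(fps_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("mixed bit universes between the two sets")
    inter = A @ B.T
    counts_a = A.sum(axis=1, keepdims=True)
    counts_b = B.sum(axis=1, keepdims=True)
    union = counts_a + counts_b.T - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


@dataclass
class ClusterAssignment:
    """Output of Butina clustering: dense cluster ids plus centroids."""

    cluster_of: dict[str, int]  # compound_key -> cluster id
    centroids: dict[int, str]  # cluster id -> centroid compound_key
    threshold: float

    def n_clusters(self) -> int:
        return len(self.centroids)

    def members_of(self, cluster_id: int) -> list[str]:
        return [k for k, c in self.cluster_of.items() if c == cluster_id]


def butina_cluster(
    fps: Sequence[Fingerprint], threshold: float
) -> ClusterAssignment:
    """Sphere-exclusion (Butina) clustering at a similarity threshold.

    ``threshold`` is a similarity (a distance cutoff of ``1 - threshold``
    in the distance parameterization). Every non-centroid member sits at
    similarity >= threshold from its cluster centroid.
    """
    if len(fps) == 0:
        raise ValueError("cannot cluster an empty fingerprint list")
    keys = [fp.compound_key for fp in fps]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate compound keys in fingerprint list")
    sim = tanimoto_matrix(fps)
    n = len(fps)
    neighbor = sim >= threshold
    np.fill_diagonal(neighbor, False)

    unassigned = np.ones(n, dtype=bool)
    cluster_of: dict[str, int] = {}
    centroids: dict[int, str] = {}
    cluster_id = 0
    while unassigned.any():
        # count unassigned neighbours among unassigned candidates only
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[centroid] & unassigned)
        centroids[cluster_id] = keys[centroid]
        cluster_of[keys[centroid]] = cluster_id
        for m in members:
            cluster_of[keys[int(m)]] = cluster_id
        unassigned[centroid] = False
        unassigned[members] = False
        cluster_id += 1
    return ClusterAssignment(cluster_of=cluster_of, centroids=centroids,
                             threshold=threshold)


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]  # compound_key -> fold index
    scheme: str
    k: int
    seed: int
    cluster_of: dict[str, int] | None = None  # set under the cluster scheme

    def fold_indices(self, keys: Sequence[str]) -> np.ndarray:
        return np.array([self.fold_of[k] for k in keys], dtype=int)

    def to_rows(self) -> list[dict]:
        return [
            {
                "compound_key": key,
                "fold": fold,
                "cluster_id": self.cluster_of.get(key) if self.cluster_of else "",
                "scheme": self.scheme,
                "seed": self.seed,
            }
            for key, fold in self.fold_of.items()
        ]


def _stratified_random_folds(
    keys: Sequence[str], labels: Sequence[str], k: int, seed: int
) -> dict[str, int]:
    """Seeded shuffle within each class, then round-robin dealing.

    The dealing position carries over between classes, so overall fold
    sizes differ by at most one and each fold's class count is within one
    of the even share.
    """
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    offset = 0
    for cls in (ACTIVE, "inactive"):
        idx = [i for i, lbl in enumerate(labels) if lbl == cls]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[keys[i]] = (j + offset) % k
        offset = (offset + len(idx)) % k
    return fold_of


def _cluster_folds(
    keys: Sequence[str], clusters: ClusterAssignment, k: int
) -> dict[str, int]:
    """Largest-first greedy packing of whole clusters into k folds."""
    members: dict[int, list[str]] = {}
    for key in keys:
        members.setdefault(clusters.cluster_of[key], []).append(key)
    order = sorted(members, key=lambda c: (-len(members[c]), c))
    sizes = [0] * k
    fold_of: dict[str, int] = {}
    for cid in order:
        fold = min(range(k), key=lambda f: (sizes[f], f))
        for key in members[cid]:
            fold_of[key] = fold
        sizes[fold] += len(members[cid])
    if min(sizes) == 0:
        raise ValueError(
            f"cannot fill {k} folds from {len(members)} clusters without an "
            "empty fold"
        )
    return fold_of


def make_folds(
    dataset: ClassifiedDataset,
    k: int,
    scheme: str,
    seed: int,
    fps: Sequence[Fingerprint] | None = None,
    threshold: float = 0.230,
    clusters: ClusterAssignment | None = None,
) -> FoldAssignment:
    """Partition a data set into k folds under the named scheme.

    ``random`` gives a seeded, class-stratified, near-equal partition.
    ``cluster`` first Butina-clusters the fingerprints (or reuses a
    provided clustering) and then packs whole clusters into folds so no
    cluster ever spans two folds.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    keys = [rec.compound_key for rec, _ in dataset.members]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate compound keys in dataset")
    if scheme == "random":
        if k > len(keys):
            raise ValueError(f"k={k} exceeds the {len(keys)} compounds")
        fold_of = _stratified_random_folds(keys, dataset.labels, k, seed)
        return FoldAssignment(fold_of=fold_of, scheme=scheme, k=k, seed=seed)

    if clusters is None:
        if fps is None:
            raise ValueError("cluster scheme needs fingerprints or a clustering")
        clusters = butina_cluster(fps, threshold)
    n_clusters = len({clusters.cluster_of[key] for key in keys})
    if k > n_clusters:
        raise ValueError(f"k={k} exceeds the {n_clusters} clusters")
    fold_of = _cluster_folds(keys, clusters, k)
    return FoldAssignment(
        fold_of=fold_of,
        scheme=scheme,
        k=k,
        seed=seed,
        cluster_of={key: clusters.cluster_of[key] for key in keys},
    )
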