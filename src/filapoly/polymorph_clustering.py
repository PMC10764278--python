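"""Polymorph identification by hierarchical clustering of filament profiles.

Filaments of one polymorph produce similar 2D class averages, so their
particles distribute similarly over 2D classes.  Polymorphs are therefore
identified by agglomerative clustering of the per-filament class-assignment
distributions:

1. pairwise cosine distances between filament profiles;
2. UPGMA (average-linkage) dendrogram over the filaments;
3. flat clusters by cutting the dendrogram at a distance threshold;
4. clusters holding fewer than ``min_particles`` particles (typically 1,000)
   are merged into the nearest surviving cluster;
5. clusters that are not yet homogeneous are re-classified (2D
   classification restricted to the cluster's particles) and re-clustered,
   iterating until every cluster is homogeneous or an iteration cap is hit.

Each filament is one observation regardless of its particle count; particle
counts enter only in small-cluster merging and downstream abundances.
Cosine distance is scale-invariant, so raw count vectors and normalised
distributions cluster identically.  All tie-breaking is by lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .particle_io import FilamentProfile

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "ClusteringConfig",
    "IterationRecord",
    "cosine_distance",
    "distance_matrix",
    "upgma_linkage",
    "flatten_dendrogram",
    "merge_small_clusters",
    "cluster_homogeneity",
    "iterate_polymorph_clustering",
    "assignment_from_labels",
]

FilamentKey = tuple[str, int]


# ---------------------------------------------------------------------------
# distances

def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance ``1 - u.v / (|u||v|)`` between nonnegative vectors.

    Zero for parallel vectors, one for vectors with disjoint support.
    Invariant to positive rescaling of either argument.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance is undefined for a zero vector")
    # clip: roundoff can push the cosine a hair past 1 for parallel vectors
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 1.0))


def distance_matrix(profiles: Sequence[FilamentProfile]) -> np.ndarray:
    """Symmetric matrix of pairwise cosine distances between profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for a distance matrix")
    X = np.stack([p.distribution for p in profiles])
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero profile vector")
    C = (X @ X.T) / np.outer(norms, norms)
    D = np.clip(1.0 - C, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


# ---------------------------------------------------------------------------
# UPGMA

@dataclass(frozen=True)
class Dendrogram:
    """Sequence of UPGMA merges over ``n_leaves`` leaves.

    Leaves are numbered ``0..n-1``; the merge at position ``i`` creates
    internal node ``n + i``.  Each entry is ``(node_a, node_b, height,
    size)`` with ``size`` the number of leaves under the new node.  UPGMA
    heights are non-decreasing (no inversions).
    """

    merges: tuple[tuple[int, int, float, int], ...]
    n_leaves: int

    def to_linkage(self) -> np.ndarray:
        """(n-1, 4) array in the conventional linkage-matrix layout."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaves_under(self, node: int) -> list[int]:
        """All leaf indices under a node (the node itself if a leaf)."""
        if node < self.n_leaves:
            return [node]
        stack, out = [node], []
        while stack:
            nd = stack.pop()
            if nd < self.n_leaves:
                out.append(nd)
            else:
                a, b, _, _ = self.merges[nd - self.n_leaves]
                stack += [a, b]
        return sorted(out)


def upgma_linkage(D: np.ndarray) -> Dendrogram:
    """UPGMA dendrogram of a symmetric distance matrix.

    The inter-cluster distance is the arithmetic mean of distances over all
    leaf pairs, maintained by the size-weighted update
    ``d(A∪B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A|+|B|)``.  At each step the
    closest active pair merges; ties break on the lowest index pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix diagonal must be zero")

    # working copy padded for internal nodes; inactive rows masked with inf
    W = np.full((2 * n - 1, 2 * n - 1), np.inf)
    W[:n, :n] = D
    np.fill_diagonal(W, np.inf)
    sizes = np.zeros(2 * n - 1, dtype=int)
    sizes[:n] = 1
    active = np.zeros(2 * n - 1, dtype=bool)
    active[:n] = True

    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        sub = W[np.ix_(active.nonzero()[0], active.nonzero()[0])]
        idx = active.nonzero()[0]
        # lowest-index tie-break: argmin scans row-major over sorted indices
        flat = np.argmin(sub)
        i, j = divmod(int(flat), sub.shape[1])
        a, b = int(idx[i]), int(idx[j])
        if a > b:
            a, b = b, a
        h = float(W[a, b])
        new = n + step
        sz = sizes[a] + sizes[b]
        # size-weighted average-linkage update
        others = active.copy()
        others[[a, b]] = False
        oi = others.nonzero()[0]
        if oi.size:
            W[new, oi] = (sizes[a] * W[a, oi] + sizes[b] * W[b, oi]) / sz
            W[oi, new] = W[new, oi]
        sizes[new] = sz
        active[[a, b]] = False
        active[new] = True
        merges.append((a, b, h, int(sz)))
    return Dendrogram(tuple(merges), n)


def flatten_dendrogram(dend: Dendrogram, threshold: float) -> np.ndarray:
    """Flat cluster labels from merges at height <= ``threshold``.

    Clusters are the connected components induced by all merges no higher
    than the threshold.  Labels are assigned 0, 1, ... in order of each
    cluster's smallest leaf index.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h, _) in enumerate(dend.merges):
        if h <= threshold:
            node = n + k
            parent[find(a)] = node
            parent[find(b)] = node

    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels[leaf] = roots[r]
    return labels


# ---------------------------------------------------------------------------
# cluster assignment, small-cluster merging, homogeneity

@dataclass
class ClusterAssignment:
    """Filament → polymorph-cluster labels with per-cluster particle counts.

    ``remainder_id`` flags the pooled cluster formed when no cluster reaches
    the minimum particle count (no large cluster exists to absorb the small
    ones).
    """

    labels: dict[FilamentKey, int]
    cluster_particle_counts: dict[int, int]
    remainder_id: int | None = None

    @property
    def total_particles(self) -> int:
        return sum(self.cluster_particle_counts.values())

    def clusters(self) -> dict[int, list[FilamentKey]]:
        out: dict[int, list[FilamentKey]] = {}
        for key, cid in self.labels.items():
            out.setdefault(cid, []).append(key)
        return {cid: sorted(mem) for cid, mem in sorted(out.items())}


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the polymorph-identification pipeline.

    flatten_threshold   cosine-distance height at which the dendrogram is cut
    min_particles       clusters with fewer particles are merged (default 1000)
    homogeneity_epsilon maximum mean pairwise cosine distance for a cluster
                        to count as homogeneous (default 0.1)
    max_iterations      cap on re-classification rounds (default 5)
    """

    flatten_threshold: float = 0.3
    min_particles: int = 1000
    homogeneity_epsilon: float = 0.1
    max_iterations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flatten_threshold <= 1.0:
            raise ValueError("flatten_threshold must be in [0, 1]")
        if self.min_particles < 1:
            raise ValueError("min_particles must be >= 1")
        if not 0.0 <= self.homogeneity_epsilon <= 1.0:
            raise ValueError("homogeneity_epsilon must be in [0, 1]")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


def assignment_from_labels(
    profiles: Sequence[FilamentProfile], labels: Sequence[int]
) -> ClusterAssignment:
    """Bundle flat labels and profile particle counts into an assignment."""
    if len(profiles) != len(labels):
        raise ValueError("labels must cover all profiles")
    lab = {p.filament_key: int(c) for p, c in zip(profiles, labels)}
    counts: dict[int, int] = {}
    for p, c in zip(profiles, labels):
        counts[int(c)] = counts.get(int(c), 0) + p.n_particles
    return ClusterAssignment(lab, counts)


def _centroid(profiles: Sequence[FilamentProfile]) -> np.ndarray:
    """Particle-weighted mean class distribution of a set of filaments."""
    w = np.array([p.n_particles for p in profiles], dtype=float)
    X = np.stack([p.distribution for p in profiles])
    return (w @ X) / w.sum()


def merge_small_clusters(
    assignment: ClusterAssignment,
    profiles: Sequence[FilamentProfile],
    min_particles: int,
) -> ClusterAssignment:
    """Merge clusters below ``min_particles`` into large neighbours.

    Each small cluster joins the surviving large cluster whose
    particle-weighted centroid is nearest by cosine distance.  If no cluster
    reaches the threshold, all filaments pool into a single remainder
    cluster, flagged by ``remainder_id``.  Total particle counts are
    conserved.
    """
    if min_particles < 1:
        raise ValueError("min_particles must be >= 1")
    by_key = {p.filament_key: p for p in profiles}
    missing = set(assignment.labels) - set(by_key)
    if missing or set(by_key) - set(assignment.labels):
        raise ValueError("assignment labels must cover exactly the given profiles")

    members: dict[int, list[FilamentProfile]] = {}
    for key, cid in assignment.labels.items():
        members.setdefault(cid, []).append(by_key[key])
    counts = {cid: sum(p.n_particles for p in mem) for cid, mem in members.items()}
    large = sorted(cid for cid, c in counts.items() if c >= min_particles)
    small = sorted(cid for cid in counts if cid not in large)

    if not small:
        return ClusterAssignment(dict(assignment.labels), counts, None)

    labels = dict(assignment.labels)
    if not large:
        rem = min(counts)
        for key in labels:
            labels[key] = rem
        return ClusterAssignment(
            labels, {rem: sum(counts.values())}, remainder_id=rem
        )

    centroids = {cid: _centroid(members[cid]) for cid in large}
    new_counts = {cid: counts[cid] for cid in large}
    for cid in small:
        c_small = _centroid(members[cid])
        # nearest large centroid; ties go to the lowest cluster id
        target = min(large, key=lambda L: (cosine_distance(c_small, centroids[L]), L))
        for p in members[cid]:
            labels[p.filament_key] = target
        new_counts[target] += counts[cid]
    return ClusterAssignment(labels, new_counts, None)


def cluster_homogeneity(profiles: Sequence[FilamentProfile]) -> float:
    """Mean pairwise cosine distance within one cluster (0 for singletons)."""
    if len(profiles) == 0:
        raise ValueError("empty cluster has no homogeneity")
    if len(profiles) == 1:
        return 0.0
    D = distance_matrix(profiles)
    n = len(profiles)
    iu = np.triu_indices(n, k=1)
    return float(D[iu].mean())


# ---------------------------------------------------------------------------
# iterated clustering / re-classification

@dataclass
class IterationRecord:
    """Audit entry for one clustering round."""

    iteration: int
    n_clusters: int
    cluster_sizes: dict[int, int]            # filaments per cluster
    cluster_particles: dict[int, int]
    homogeneities: dict[int, float]
    reclassified: list[int] = field(default_factory=list)


Reclassifier = Callable[
    [Sequence[FilamentKey], int],
    tuple[Mapping[FilamentKey, np.ndarray], int],
]


def _cluster_once(
    profiles: Sequence[FilamentProfile], config: ClusteringConfig
) -> ClusterAssignment:
    """One cluster → flatten → merge-small pass over a profile set."""
    if len(profiles) == 1:
        p = profiles[0]
        return ClusterAssignment({p.filament_key: 0}, {0: p.n_particles})
    D = distance_matrix(profiles)
    labels = flatten_dendrogram(upgma_linkage(D), config.flatten_threshold)
    return merge_small_clusters(
        assignment_from_labels(profiles, labels), profiles, config.min_particles
    )


def iterate_polymorph_clustering(
    profiles: Sequence[FilamentProfile],
    reclassify: Reclassifier | None,
    config: ClusteringConfig,
) -> tuple[ClusterAssignment, list[IterationRecord]]:
    """Iterated polymorph identification over filament profiles.

    An initial cluster → flatten → merge pass is always performed.  Then,
    for up to ``config.max_iterations`` rounds, every cluster whose mean
    pairwise cosine distance exceeds ``homogeneity_epsilon`` has its
    filaments re-classified through the ``reclassify`` callback (in real use
    an external 2D classification of the cluster's particles) and is
    re-clustered on the resulting profiles — each such cluster in its own
    class space, since re-classification changes the class inventory.
    Iteration stops early once every cluster is homogeneous.

    ``reclassify(keys, round_index)`` must return ``(assignments, K)`` where
    ``assignments`` maps each filament key to a 1-based class-id array (one
    entry per particle) and ``K`` is the new class count.

    Returns the final assignment (cluster ids relabelled 0, 1, ... by
    smallest member filament key) and a per-iteration audit log.
    """
    if not profiles:
        return ClusterAssignment({}, {}), []
    prof_by_key: dict[FilamentKey, FilamentProfile] = {
        p.filament_key: p for p in profiles
    }
    if len(prof_by_key) != len(profiles):
        raise ValueError("duplicate filament keys in profiles")

    # cluster membership is tracked by key; profiles are per-cluster local
    assignment = _cluster_once(profiles, config)
    log: list[IterationRecord] = []

    for it in range(1, config.max_iterations + 1):
        clusters = assignment.clusters()
        homog = {
            cid: cluster_homogeneity([prof_by_key[k] for k in mem])
            for cid, mem in clusters.items()
        }
        rec = IterationRecord(
            iteration=it,
            n_clusters=len(clusters),
            cluster_sizes={cid: len(mem) for cid, mem in clusters.items()},
            cluster_particles=dict(assignment.cluster_particle_counts),
            homogeneities=homog,
        )
        bad = [cid for cid, h in homog.items() if h > config.homogeneity_epsilon]
        log.append(rec)
        if not bad:
            break

        from .particle_io import FilamentProfile as _FP

        pieces: list[tuple[FilamentKey, int]] = []  # (key, provisional cluster)
        next_cid = 0
        for cid, mem in clusters.items():
            if cid not in bad:
                for k in mem:
                    pieces.append((k, next_cid))
                next_cid += 1
                continue
            if reclassify is None:
                raise ValueError(
                    f"iteration {it}: cluster {cid} is inhomogeneous but no "
                    "reclassifier was provided"
                )
            rec.reclassified.append(cid)
            try:
                new_assign, K = reclassify(mem, it)
            except Exception as exc:
                raise RuntimeError(
                    f"reclassify failed at iteration {it}, cluster {cid}"
                ) from exc
            new_profiles = []
            for k in mem:
                cls = np.asarray(new_assign[k], dtype=int)
                usable = cls[cls >= 1]
                counts = np.bincount(usable - 1, minlength=K).astype(float)
                new_profiles.append(_FP(k, int(usable.size), counts / usable.size))
                prof_by_key[k] = new_profiles[-1]
            sub = _cluster_once(new_profiles, config)
            remap: dict[int, int] = {}
            for k, sub_cid in sub.labels.items():
                if sub_cid not in remap:
                    remap[sub_cid] = next_cid
                    next_cid += 1
                pieces.append((k, remap[sub_cid]))
        labels = {k: c for k, c in pieces}
        counts: dict[int, int] = {}
        for k, c in pieces:
            counts[c] = counts.get(c, 0) + prof_by_key[k].n_particles
        assignment = ClusterAssignment(labels, counts)

    # deterministic relabelling by smallest member key
    order = sorted(assignment.clusters().items(), key=lambda kv: kv[1][0])
    relabel = {old: new for new, (old, _) in enumerate(order)}
    final = ClusterAssignment(
        {k: relabel[c] for k, c in assignment.labels.items()},
        {relabel[c]: n for c, n in assignment.cluster_particle_counts.items()},
        remainder_id=(
            relabel[assignment.remainder_id]
            if assignment.remainder_id is not None
            else None
        ),
    )
    return final, log
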