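"""Cluster aligned LC-MS features across datasets and score the clusters.

Features from all datasets are clustered agglomeratively in (mass, NET)
space under a normalized L2 distance d = sqrt((dppm/mass_tol)^2 +
(dnet/net_tol)^2), so a unit distance means "at tolerance" on one axis.

* **single linkage** merges the closest pair of clusters, allowed only
  when that closest member pair is within both the ppm and NET gates;
* **average linkage** merges on centroid distance, gated on the centroid
  deltas.

For speed the feature list is first *partitioned by mass*: sorted
ascending, a boundary is placed at any consecutive gap above the mass
tolerance.  No merge can ever cross such a gap, so clustering each
partition independently is exactly equivalent to clustering everything
at once (asserted in the tests).

Scores: *tightness* is the mean normalized distance of members to the
cluster centroid (0 for singletons; smaller = tighter).  *Ambiguity* is
the minimum member-pair distance to any neighboring cluster (centroid
within twice both tolerances); small values mean a nearby cluster could
be confused with this one, ``inf`` means no neighbor at all.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from sklearn.base import BaseEstimator

from .models import FeatureCluster, LCMSFeature
from .parameters import ClusteringParameters


def _feature_distance(
    mass_a: float, net_a: float, mass_b: float, net_b: float,
    mass_tol_ppm: float, net_tol: float,
) -> float:
    d_ppm = 1e6 * abs(mass_a - mass_b) / ((mass_a + mass_b) / 2.0)
    d_net = abs(net_a - net_b)
    return math.sqrt((d_ppm / mass_tol_ppm) ** 2 + (d_net / net_tol) ** 2)


def _within_gates(
    mass_a: float, net_a: float, mass_b: float, net_b: float,
    mass_tol_ppm: float, net_tol: float,
) -> bool:
    d_ppm = 1e6 * abs(mass_a - mass_b) / ((mass_a + mass_b) / 2.0)
    return d_ppm <= mass_tol_ppm and abs(net_a - net_b) <= net_tol


def partition_by_mass(
    features: list[LCMSFeature], mass_tol_ppm: float
) -> list[list[LCMSFeature]]:
    """Split mass-sorted features at consecutive gaps above the tolerance."""
    ordered = sorted(
        features, key=lambda f: (f.monoisotopic_mass, f.net, f.dataset_id, f.lcms_id)
    )
    partitions: list[list[LCMSFeature]] = []
    current: list[LCMSFeature] = []
    prev_mass = None
    for f in ordered:
        if prev_mass is not None and 1e6 * (f.monoisotopic_mass - prev_mass) / prev_mass > mass_tol_ppm:
            partitions.append(current)
            current = []
        current.append(f)
        prev_mass = f.monoisotopic_mass
    if current:
        partitions.append(current)
    return partitions


def _single_linkage(partition, mass_tol_ppm, net_tol) -> list[list[int]]:
    """Connected components of the gate graph = gated single linkage.

    A merge is allowed exactly when the closest cross pair satisfies both
    gates, so two groups end up together iff some member pair does.
    """
    n = len(partition)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    masses = [f.monoisotopic_mass for f in partition]
    nets = [f.net for f in partition]
    # partition is mass-sorted; gate window closes once dppm > tol
    for a in range(n):
        for b in range(a + 1, n):
            if 1e6 * (masses[b] - masses[a]) / ((masses[a] + masses[b]) / 2.0) > mass_tol_ppm:
                break
            if abs(nets[a] - nets[b]) <= net_tol:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def _centroid(partition, idx) -> tuple[float, float]:
    return (
        float(np.median([partition[i].monoisotopic_mass for i in idx])),
        float(np.median([partition[i].net for i in idx])),
    )


def _average_linkage(partition, mass_tol_ppm, net_tol) -> list[list[int]]:
    """Iterative centroid-linkage agglomeration with gates on centroid deltas.

    Merges the minimum-centroid-distance allowed pair, recomputes the
    (median, median) centroid, and repeats until no allowed merge remains.
    Ties break on the lowest (cluster_id_a, cluster_id_b).
    """
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(partition))}
    centroids: dict[int, tuple[float, float]] = {
        i: (partition[i].monoisotopic_mass, partition[i].net) for i in range(len(partition))
    }
    while True:
        best = None  # (distance, id_a, id_b)
        ids = sorted(clusters)
        for ia, ib in itertools.combinations(ids, 2):
            (ma, na), (mb, nb) = centroids[ia], centroids[ib]
            if not _within_gates(ma, na, mb, nb, mass_tol_ppm, net_tol):
                continue
            d = _feature_distance(ma, na, mb, nb, mass_tol_ppm, net_tol)
            if best is None or (d, ia, ib) < best:
                best = (d, ia, ib)
        if best is None:
            break
        _, ia, ib = best
        clusters[ia] = clusters[ia] + clusters[ib]
        del clusters[ib], centroids[ib]
        centroids[ia] = _centroid(partition, clusters[ia])
    return [clusters[k] for k in sorted(clusters)]


def cluster_partition(
    partition: list[LCMSFeature],
    method: str = "single",
    mass_tol_ppm: float = 10.0,
    net_tol: float = 0.03,
    first_id: int = 0,
    score_ambiguity: bool = True,
) -> list[FeatureCluster]:
    """Cluster one mass partition (mass-sorted, as produced by
    :func:`partition_by_mass`); see the module docstring for linkages."""
    if method == "single":
        groups = _single_linkage(partition, mass_tol_ppm, net_tol)
    elif method == "average":
        groups = _average_linkage(partition, mass_tol_ppm, net_tol)
    else:
        raise ValueError(f"unknown linkage method {method!r}")
    clusters = []
    for k, idx in enumerate(groups):
        members = [partition[i] for i in idx]
        cmass = float(np.median([m.monoisotopic_mass for m in members]))
        cnet = float(np.median([m.net for m in members]))
        clusters.append(
            FeatureCluster(
                cluster_id=first_id + k,
                members=members,
                centroid_mass=cmass,
                centroid_net=cnet,
            )
        )
    for c in clusters:
        c.tightness = tightness_score(c, mass_tol_ppm, net_tol)
    if score_ambiguity:
        assign_ambiguity(clusters, mass_tol_ppm, net_tol)
    return clusters


def assign_ambiguity(
    clusters: list[FeatureCluster], mass_tol_ppm: float, net_tol: float
) -> None:
    """Set every cluster's ambiguity, searching neighbors globally.

    Neighbor search is windowed on centroid mass (sorted), since neighbors
    live within 2x the mass tolerance.
    """
    order = sorted(range(len(clusters)), key=lambda i: clusters[i].centroid_mass)
    masses = [clusters[i].centroid_mass for i in order]
    for pos, i in enumerate(order):
        c = clusters[i]
        best = math.inf
        for step in (1, -1):
            q = pos + step
            while 0 <= q < len(order):
                d_ppm = 1e6 * abs(masses[q] - masses[pos]) / ((masses[q] + masses[pos]) / 2.0)
                if d_ppm > 2 * mass_tol_ppm:
                    break
                other = clusters[order[q]]
                if abs(other.centroid_net - c.centroid_net) <= 2 * net_tol:
                    for m in c.members:
                        for o in other.members:
                            d = _feature_distance(
                                m.monoisotopic_mass, m.net,
                                o.monoisotopic_mass, o.net,
                                mass_tol_ppm, net_tol,
                            )
                            if d < best:
                                best = d
                q += step
        c.ambiguity = best


def cluster_all(
    features: list[LCMSFeature],
    params: ClusteringParameters | None = None,
    partition: bool = True,
) -> list[FeatureCluster]:
    """Cluster all datasets' aligned features, with mass partitioning.

    ``partition=False`` runs the same linkage on the full feature list in
    one piece; the result is identical because partition boundaries exceed
    the merge gate by construction (kept as a cross-check).
    """
    params = params or ClusteringParameters()
    if not features:
        return []
    if partition:
        parts = partition_by_mass(features, params.mass_tolerance_ppm)
    else:
        parts = [sorted(features, key=lambda f: (f.monoisotopic_mass, f.net,
                                                 f.dataset_id, f.lcms_id))]
    clusters: list[FeatureCluster] = []
    for part in parts:
        clusters.extend(
            cluster_partition(
                part,
                method=params.method,
                mass_tol_ppm=params.mass_tolerance_ppm,
                net_tol=params.net_tolerance,
                first_id=len(clusters),
                score_ambiguity=False,
            )
        )
    # ambiguity is scored globally: a neighboring cluster (within 2x the
    # gates) can sit just across a partition boundary (boundaries only
    # guarantee a gap of 1x the mass tolerance)
    assign_ambiguity(clusters, params.mass_tolerance_ppm, params.net_tolerance)
    return clusters


def tightness_score(
    cluster: FeatureCluster, mass_tol_ppm: float, net_tol: float
) -> float:
    """Mean normalized L2 distance of members to the cluster centroid."""
    if cluster.member_count == 1:
        return 0.0
    dists = [
        _feature_distance(
            m.monoisotopic_mass, m.net, cluster.centroid_mass, cluster.centroid_net,
            mass_tol_ppm, net_tol,
        )
        for m in cluster.members
    ]
    return float(np.mean(dists))


def ambiguity_score(
    cluster: FeatureCluster,
    all_clusters: list[FeatureCluster],
    mass_tol_ppm: float,
    net_tol: float,
) -> float:
    """Minimum member-pair distance to any neighboring cluster.

    Neighbors are clusters whose centroid lies within 2x both tolerances.
    Returns ``inf`` when the cluster has no neighbor (maximally
    unambiguous).
    """
    best = math.inf
    for other in all_clusters:
        if other is cluster or other.cluster_id == cluster.cluster_id:
            continue
        d_ppm = 1e6 * abs(other.centroid_mass - cluster.centroid_mass) / (
            (other.centroid_mass + cluster.centroid_mass) / 2.0
        )
        if d_ppm > 2 * mass_tol_ppm or abs(other.centroid_net - cluster.centroid_net) > 2 * net_tol:
            continue
        for m in cluster.members:
            for o in other.members:
                d = _feature_distance(
                    m.monoisotopic_mass, m.net, o.monoisotopic_mass, o.net,
                    mass_tol_ppm, net_tol,
                )
                if d < best:
                    best = d
    return best


class FeatureClusterer(BaseEstimator):
    """Estimator facade over :func:`cluster_all`.

    After ``fit``: ``clusters_`` (list of :class:`FeatureCluster`) and
    ``labels_`` (cluster id per input feature, in input order).
    """

    def __init__(
        self,
        method: str = "single",
        mass_tolerance_ppm: float = 10.0,
        net_tolerance: float = 0.03,
        partition: bool = True,
    ):
        self.method = method
        self.mass_tolerance_ppm = mass_tolerance_ppm
        self.net_tolerance = net_tolerance
        self.partition = partition

    def fit(self, X: list[LCMSFeature], y=None):
        params = ClusteringParameters(
            method=self.method,
            mass_tolerance_ppm=self.mass_tolerance_ppm,
            net_tolerance=self.net_tolerance,
        )
        self.clusters_ = cluster_all(list(X), params, partition=self.partition)
        by_identity = {}
        for c in self.clusters_:
            for m in c.members:
                by_identity[id(m)] = c.cluster_id
        self.labels_ = np.array([by_identity[id(f)] for f in X])
        return self

    def fit_predict(self, X: list[LCMSFeature], y=None) -> np.ndarray:
        return self.fit(X).labels_
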