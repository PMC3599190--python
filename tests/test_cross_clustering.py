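import math

import numpy as np
import pytest

import lcmsalign as la
from lcmsalign.cross_clustering import (
    FeatureClusterer,
    ambiguity_score,
    assign_ambiguity,
    cluster_all,
    cluster_partition,
    partition_by_mass,
    tightness_score,
)
from lcmsalign.parameters import ClusteringParameters

from conftest import make_lcms_feature, random_lcms_features
from oracles import naive_single_linkage_lcms


class TestPartition:
    def test_gap_rule(self):
        feats = [
            make_lcms_feature(lcms_id=0, monoisotopic_mass=100.000000),
            make_lcms_feature(lcms_id=1, monoisotopic_mass=100.000500),  # 5 ppm gap
            make_lcms_feature(lcms_id=2, monoisotopic_mass=200.0),
        ]
        parts = partition_by_mass(feats, mass_tol_ppm=10)
        assert [len(p) for p in parts] == [2, 1]
        assert {f.lcms_id for f in parts[0]} == {0, 1}

    def test_identical_masses_one_partition(self):
        feats = [make_lcms_feature(lcms_id=i) for i in range(5)]
        assert len(partition_by_mass(feats, 10)) == 1

    def test_partitions_cover_and_are_disjoint(self):
        rng = np.random.default_rng(4)
        feats = random_lcms_features(rng, 200, ["a", "b"])
        parts = partition_by_mass(feats, 10)
        seen = [id(f) for p in parts for f in p]
        assert sorted(seen) == sorted(id(f) for f in feats)
        assert len(set(seen)) == len(feats)


class TestClusterPartition:
    def test_within_both_gates_merges(self):
        feats = [
            make_lcms_feature(dataset_id="a", lcms_id=0,
                              monoisotopic_mass=1000.0, net=0.500),
            make_lcms_feature(dataset_id="b", lcms_id=1,
                              monoisotopic_mass=1000.002, net=0.505),
        ]
        clusters = cluster_partition(sorted(feats, key=lambda f: f.monoisotopic_mass))
        assert len(clusters) == 1
        assert clusters[0].member_count == 2
        assert clusters[0].tightness > 0

    def test_net_gate_blocks(self):
        feats = [
            make_lcms_feature(dataset_id="a", lcms_id=0, net=0.50),
            make_lcms_feature(dataset_id="b", lcms_id=1, net=0.60),
        ]
        clusters = cluster_partition(feats, net_tol=0.03)
        assert len(clusters) == 2

    def test_single_linkage_oracle_equivalence(self):
        rng = np.random.default_rng(17)
        feats = random_lcms_features(rng, 400, list("abcde"),
                                     mass_range=(1000.0, 1000.6))
        ordered = sorted(feats, key=lambda f: f.monoisotopic_mass)
        clusters = cluster_partition(ordered, method="single")
        ours = {
            frozenset(ordered.index(m) for m in c.members) for c in clusters
        }
        assert ours == naive_single_linkage_lcms(ordered, 10.0, 0.03)

    def test_average_linkage_respects_centroid_gates(self):
        feats = [
            make_lcms_feature(dataset_id="a", lcms_id=0, net=0.500),
            make_lcms_feature(dataset_id="b", lcms_id=1, net=0.520),
            make_lcms_feature(dataset_id="c", lcms_id=2, net=0.545),
        ]
        # chained singles would merge all three; average linkage stops when
        # the centroid step exceeds the NET gate
        clusters = cluster_partition(feats, method="average", net_tol=0.022)
        sizes = sorted(c.member_count for c in clusters)
        assert sizes == [1, 2]


class TestClusterAll:
    def test_partition_equals_no_partition(self):
        rng = np.random.default_rng(23)
        feats = random_lcms_features(rng, 500, list("abcde"))
        with_parts = cluster_all(feats, partition=True)
        without = cluster_all(feats, partition=False)
        key = lambda cs: {frozenset(id(m) for m in c.members) for c in cs}
        assert key(with_parts) == key(without)

    def test_every_feature_in_exactly_one_cluster(self):
        rng = np.random.default_rng(29)
        feats = random_lcms_features(rng, 300, list("abc"))
        clusters = cluster_all(feats)
        seen = [id(m) for c in clusters for m in c.members]
        assert sorted(seen) == sorted(id(f) for f in feats)

    def test_empty_input(self):
        assert cluster_all([]) == []

    def test_estimator_labels_match_clusters(self):
        rng = np.random.default_rng(31)
        feats = random_lcms_features(rng, 100, list("ab"))
        clusterer = FeatureClusterer().fit(feats)
        for f, label in zip(feats, clusterer.labels_):
            cluster = next(c for c in clusterer.clusters_ if c.cluster_id == label)
            assert any(m is f for m in cluster.members)


class TestScores:
    def test_singleton_tightness_zero(self):
        c = la.FeatureCluster(0, [make_lcms_feature()], 1000.0, 0.5)
        assert tightness_score(c, 10, 0.03) == 0.0

    def test_symmetric_pair_hand_value(self):
        # two members symmetric about the centroid, each at exactly half
        # the mass gate: per-member normalized distance 0.5, mean 0.5
        tol_ppm = 10.0
        m = 1000.0
        half = m * (tol_ppm / 2) * 1e-6
        a = make_lcms_feature(dataset_id="a", lcms_id=0, monoisotopic_mass=m - half)
        b = make_lcms_feature(dataset_id="b", lcms_id=1, monoisotopic_mass=m + half)
        c = la.FeatureCluster(0, [a, b], centroid_mass=m, centroid_net=0.5)
        assert tightness_score(c, tol_ppm, 0.03) == pytest.approx(0.5, rel=1e-3)

    def test_farther_member_never_decreases_tightness(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            members = [
                make_lcms_feature(
                    lcms_id=i,
                    monoisotopic_mass=1000.0 + float(rng.normal(0, 0.002)),
                    net=0.5 + float(rng.normal(0, 0.005)),
                )
                for i in range(4)
            ]
            centroid_mass = float(np.median([m.monoisotopic_mass for m in members]))
            centroid_net = float(np.median([m.net for m in members]))
            base = la.FeatureCluster(0, members, centroid_mass, centroid_net)
            t0 = tightness_score(base, 10, 0.03)
            # add a member farther from the (fixed) centroid than the mean
            far = make_lcms_feature(
                lcms_id=99, monoisotopic_mass=centroid_mass * (1 + 8e-6),
                net=centroid_net + 0.02,
            )
            grown = la.FeatureCluster(0, members + [far], centroid_mass, centroid_net)
            assert tightness_score(grown, 10, 0.03) >= t0

    def test_lone_cluster_infinite_ambiguity(self):
        c = la.FeatureCluster(0, [make_lcms_feature()], 1000.0, 0.5)
        assert ambiguity_score(c, [c], 10, 0.03) == math.inf

    def test_just_beyond_gate_ambiguity_value(self):
        # two singletons separated by 1.1x the mass gate, same NET:
        # normalized separation = 1.1
        tol_ppm = 10.0
        m = 1000.0
        a = make_lcms_feature(dataset_id="a", lcms_id=0, monoisotopic_mass=m)
        b = make_lcms_feature(
            dataset_id="b", lcms_id=1,
            monoisotopic_mass=m * (1 + 1.1 * tol_ppm * 1e-6),
        )
        ca = la.FeatureCluster(0, [a], a.monoisotopic_mass, 0.5)
        cb = la.FeatureCluster(1, [b], b.monoisotopic_mass, 0.5)
        va = ambiguity_score(ca, [ca, cb], tol_ppm, 0.03)
        vb = ambiguity_score(cb, [ca, cb], tol_ppm, 0.03)
        assert va == pytest.approx(1.1, rel=1e-3)
        assert va == vb  # symmetric for mutually nearest clusters

    def test_assign_ambiguity_matches_direct_scores(self):
        rng = np.random.default_rng(41)
        feats = random_lcms_features(rng, 120, list("ab"),
                                     mass_range=(1000.0, 1000.2))
        clusters = cluster_all(feats)
        direct = [ambiguity_score(c, clusters, 10, 0.03) for c in clusters]
        assert [c.ambiguity for c in clusters] == pytest.approx(direct)

    def test_ground_truth_recovery_with_ambiguity_filter(self, small_experiment):
        """Filtering to all-dataset clusters with ambiguity > 1 recovers
        exactly the planted analyte set when noise is within half-gates."""
        state = small_experiment["state"]
        truth = small_experiment["truth"]
        n_datasets = len(truth.datasets)
        selected = [
            c for c in state.clusters
            if c.dataset_count == n_datasets and c.ambiguity > 1
        ]
        assert len(selected) == len(truth.analytes)
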