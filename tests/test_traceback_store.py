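import math

import numpy as np
import pytest

import lcmsalign as la
from lcmsalign.store import AnalysisState, ResultsStore, persist_results
from lcmsalign.traceback_queries import (
    export_cluster_spectra,
    select_target_clusters,
    spectra_for_cluster,
    spectra_for_cluster_sql,
)

from conftest import make_lcms_feature


def tiny_state():
    """Two clusters; members carry spectrum links {s1} / {s2, s3} / {}."""
    f1 = make_lcms_feature(dataset_id="a", lcms_id=0, monoisotopic_mass=1000.0)
    f2 = make_lcms_feature(dataset_id="b", lcms_id=0, monoisotopic_mass=1000.001)
    f3 = make_lcms_feature(dataset_id="a", lcms_id=1, monoisotopic_mass=1200.0)
    f1.spectrum_ids = [1]
    f2.spectrum_ids = [2, 3]
    spectra = {
        "a": [
            la.MSnSpectrum("a", 1, 101, 2, 501.0, 2, np.array([[100.0, 1.0]])),
        ],
        "b": [
            la.MSnSpectrum("b", 2, 102, 2, 501.0, 2, np.array([[110.0, 1.0]])),
            la.MSnSpectrum("b", 3, 103, 2, 501.1, 2, np.array([[120.0, 1.0]])),
        ],
    }
    clusters = [
        la.FeatureCluster(0, [f1, f2], 1000.0005, 0.5, tightness=0.1, ambiguity=math.inf),
        la.FeatureCluster(1, [f3], 1200.0, 0.5, tightness=0.0, ambiguity=math.inf),
    ]
    state = AnalysisState()
    state.dataset_info = {"a": {}, "b": {}}
    state.lcms_features = {"a": [f1, f3], "b": [f2]}
    state.spectra = spectra
    state.clusters = clusters
    return state


class TestInMemoryTraceback:
    def test_union_of_member_links(self):
        records = spectra_for_cluster(0, tiny_state())
        assert len(records) == 3
        assert {r.spectrum_id for r in records} == {1, 2, 3}

    def test_unlinked_members_give_empty(self):
        assert spectra_for_cluster(1, tiny_state()) == []

    def test_unknown_cluster_rejected(self):
        with pytest.raises(KeyError):
            spectra_for_cluster(99, tiny_state())


class TestStore:
    def test_sql_equals_memory_for_every_cluster(self, tmp_path, small_experiment):
        state = small_experiment["state"]
        db = small_experiment["results_dir"] / "results.db3"
        with ResultsStore(db) as store:
            for c in state.clusters:
                memory = [
                    (r.dataset_id, r.lcms_id, r.spectrum_id, r.scan)
                    for r in spectra_for_cluster(c.cluster_id, state)
                ]
                sql = [
                    (r.dataset_id, r.lcms_id, r.spectrum_id, r.scan)
                    for r in spectra_for_cluster_sql(c.cluster_id, store)
                ]
                assert memory == sql

    def test_every_linked_spectrum_reachable(self, small_experiment):
        """Bidirectional audit: a spectrum is reachable from a cluster iff
        one of that cluster's members links to it."""
        state = small_experiment["state"]
        reachable = set()
        for c in state.clusters:
            for r in spectra_for_cluster(c.cluster_id, state):
                reachable.add((r.dataset_id, r.spectrum_id))
        linked = {
            (ds, sid)
            for ds, feats in state.lcms_features.items()
            for f in feats
            for sid in f.spectrum_ids
        }
        assert reachable == linked

    def test_empty_analysis_has_all_tables(self, tmp_path):
        db = tmp_path / "empty.db3"
        persist_results(AnalysisState(), db)
        with ResultsStore(db) as store:
            for table in (
                "datasets", "ms_features", "lcms_features", "feature_members",
                "clusters", "cluster_members", "amt_tags", "matches",
                "spectra", "spectrum_links", "alignments", "parameters",
            ):
                if table == "parameters":
                    assert store.table_count(table) > 0  # defaults persisted
                else:
                    assert store.table_count(table) == 0

    def test_existing_file_refused_without_overwrite(self, tmp_path):
        db = tmp_path / "x.db3"
        persist_results(AnalysisState(), db)
        with pytest.raises(FileExistsError):
            persist_results(AnalysisState(), db)
        persist_results(AnalysisState(), db, overwrite=True)

    def test_parameters_round_trip(self, tmp_path):
        state = AnalysisState()
        state.parameters.clustering.method = "average"
        state.parameters.spectral.similarity_threshold = 0.85
        state.parameters.loading_filters.max_isotopic_fit = None
        db = tmp_path / "p.db3"
        persist_results(state, db)
        with ResultsStore(db) as store:
            stored = store.parameters()
        for key, value in stored.items():
            if key == "seed":
                continue
            section, name = key.split(".")
            expected = state.parameters.to_dict()[section][name]
            assert value == ("" if expected is None else str(expected))
        assert stored["clustering.method"] == "average"
        assert stored["spectral.similarity_threshold"] == "0.85"

    def test_infinite_ambiguity_survives_round_trip(self, tmp_path):
        state = tiny_state()
        db = tmp_path / "inf.db3"
        persist_results(state, db)
        with ResultsStore(db) as store:
            row = store.cluster_row(1)
        assert math.isinf(row["ambiguity"])


class TestExport:
    def test_block_count_and_pepmass(self, tmp_path):
        from lcmsalign.io_formats import read_spectra

        state = tiny_state()
        path = tmp_path / "out.mgf"
        n = export_cluster_spectra([0], state, path)
        assert n == 3
        back = read_spectra(path)
        assert len(back) == 3
        assert sorted(s.precursor_mz for s in back) == [501.0, 501.0, 501.1]

    def test_round_trip_peak_lists(self, tmp_path, small_experiment):
        from lcmsalign.io_formats import read_spectra

        state = small_experiment["state"]
        target = next(
            c.cluster_id for c in state.clusters
            if spectra_for_cluster(c.cluster_id, state)
        )
        path = tmp_path / "cluster.mgf"
        export_cluster_spectra([target], state, path)
        back = read_spectra(path)
        records = spectra_for_cluster(target, state)
        assert len(back) == len(records)
        source = {
            (r.dataset_id, r.spectrum_id): s
            for r in records
            for s in state.spectra[r.dataset_id]
            if s.spectrum_id == r.spectrum_id
        }
        assert len(source) == len(records)
        exported = sorted(back, key=lambda s: (s.scan, s.precursor_mz))
        expected = sorted(source.values(), key=lambda s: (s.scan, s.precursor_mz))
        for got, want in zip(exported, expected):
            np.testing.assert_allclose(got.peaks, want.peaks, atol=1e-5)

    def test_empty_selection_valid_empty_mgf(self, tmp_path):
        path = tmp_path / "empty.mgf"
        assert export_cluster_spectra([], tiny_state(), path) == 0
        from lcmsalign.io_formats import read_spectra

        assert read_spectra(path) == []


class TestSelectTargets:
    def _clusters(self):
        out = []
        for cid, (nds, tight, amb) in enumerate(
            [(1, 0.0, math.inf), (2, 0.2, 0.5), (3, 0.4, 2.0), (3, 0.05, 1.5)]
        ):
            members = [
                make_lcms_feature(dataset_id=f"d{k}", lcms_id=cid) for k in range(nds)
            ]
            out.append(
                la.FeatureCluster(cid, members, 1000.0 + cid, 0.5,
                                  tightness=tight, ambiguity=amb)
            )
        return out

    def test_no_limits_returns_all(self):
        assert select_target_clusters(self._clusters()) == [0, 1, 2, 3]

    def test_impossible_ambiguity_returns_empty(self):
        assert select_target_clusters(self._clusters(), min_ambiguity=math.inf) == [0]
        # only the sentinel-infinite cluster survives an infinite cutoff

    def test_filters_compose_monotonically(self):
        clusters = self._clusters()
        loose = set(select_target_clusters(clusters, min_datasets=2))
        tighter = set(select_target_clusters(clusters, min_datasets=2, min_ambiguity=1.0))
        tightest = set(
            select_target_clusters(clusters, min_datasets=3, min_ambiguity=1.0,
                                   max_tightness=0.1)
        )
        assert tightest <= tighter <= loose

    def test_unidentified_only_drops_unambiguous_matches(self):
        clusters = self._clusters()
        matches = [la.TagMatch(2, "t", 0, 0, stac=0.9, uniqueness=0.8)]
        kept = select_target_clusters(clusters, unidentified_only=True, matches=matches)
        assert 2 not in kept and 3 in kept

    def test_ground_truth_recovery_with_all_dataset_filter(self, small_experiment):
        state = small_experiment["state"]
        truth = small_experiment["truth"]
        selected = select_target_clusters(
            state.clusters, min_datasets=len(truth.datasets)
        )
        assert len(selected) == len(truth.analytes)
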