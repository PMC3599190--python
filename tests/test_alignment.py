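import numpy as np
import pytest

import lcmsalign as la
from lcmsalign.alignment import (
    AlignmentError,
    LCMSWarpAligner,
    compute_mass_correction,
    compute_raw_net,
    compute_warp,
    find_anchor_matches,
)
from lcmsalign.models import AnchorMatch
from lcmsalign.parameters import AlignmentParameters

from conftest import make_lcms_feature
from oracles import brute_force_anchor_pairs


def features_at_scans(scans):
    return [
        make_lcms_feature(lcms_id=i, scan=s, monoisotopic_mass=1000.0 + i)
        for i, s in enumerate(scans)
    ]


class TestRawNet:
    def test_min_max_definition(self):
        feats = compute_raw_net(features_at_scans([1, 50, 100]))
        nets = [f.net for f in feats]
        assert nets == pytest.approx([0.0, 49 / 99, 1.0])

    def test_monotone_in_scan(self):
        rng = np.random.default_rng(0)
        scans = rng.choice(np.arange(1, 5000), size=50, replace=False)
        feats = compute_raw_net(features_at_scans(list(scans)))
        order = np.argsort(scans)
        nets = np.array([f.net for f in feats])[order]
        assert np.all(np.diff(nets) > 0)

    def test_affine_scan_relabeling_invariance(self):
        scans = [3, 40, 77, 200, 512]
        nets_a = [f.net for f in compute_raw_net(features_at_scans(scans))]
        nets_b = [
            f.net
            for f in compute_raw_net(features_at_scans([2 * s + 7 for s in scans]))
        ]
        assert nets_a == pytest.approx(nets_b, abs=1e-12)

    def test_degenerate_single_scan_warns(self, caplog):
        feats = compute_raw_net(features_at_scans([10, 10, 10]))
        assert all(f.net == 0.5 for f in feats)


class TestAnchors:
    def test_identity_lists_include_self_pairs(self):
        feats = compute_raw_net(features_at_scans(range(10, 110, 10)))
        anchors = find_anchor_matches(feats, feats, mass_tol_ppm=10)
        assert len(anchors) >= len(feats)
        zero = [a for a in anchors if a.delta_ppm == 0.0]
        assert len(zero) >= len(feats)

    def test_disjoint_mass_ranges_error(self):
        a = [make_lcms_feature(lcms_id=0, monoisotopic_mass=500.0, net=0.5)]
        b = [make_lcms_feature(lcms_id=0, monoisotopic_mass=900.0, net=0.5)]
        with pytest.raises(AlignmentError, match="tolerance"):
            find_anchor_matches(a, b, mass_tol_ppm=10)

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(21)
        alignee = [
            make_lcms_feature(
                lcms_id=i,
                monoisotopic_mass=float(rng.uniform(1000, 1000.2)),
                net=float(rng.uniform(0, 1)),
            )
            for i in range(200)
        ]
        baseline = [
            make_lcms_feature(
                lcms_id=i,
                monoisotopic_mass=float(rng.uniform(1000, 1000.2)),
                net=float(rng.uniform(0, 1)),
            )
            for i in range(150)
        ]
        anchors = find_anchor_matches(alignee, baseline, mass_tol_ppm=10)
        coords = [(f.monoisotopic_mass, f.net) for f in baseline]
        assert len(anchors) == len(brute_force_anchor_pairs(alignee, coords, 10))


def synthetic_anchors(warp, n=400, seed=3, ppm=0.0, sd_ppm=0.5):
    """Anchors whose baseline NET is warp(alignee NET)."""
    rng = np.random.default_rng(seed)
    xs = rng.uniform(0.02, 0.98, size=n)
    return [
        AnchorMatch(
            alignee_net=float(x),
            baseline_net=float(min(max(warp(x), 0.0), 1.0)),
            delta_ppm=float(ppm + rng.normal(0, sd_ppm)),
            alignee_mass=1000.0,
        )
        for x in xs
    ]


class TestWarp:
    def test_self_alignment_identity(self):
        anchors = synthetic_anchors(lambda x: x)
        fn = compute_warp(anchors, AlignmentParameters())
        grid = np.linspace(0, 1, 1000)
        assert np.mean(np.abs(fn.warp(grid) - grid)) < 1.0 / 100

    def test_constant_shift_recovery(self):
        anchors = synthetic_anchors(lambda x: min(x + 0.1, 1.0))
        fn = compute_warp(anchors, AlignmentParameters())
        interior = np.linspace(0.1, 0.8, 200)
        err = np.abs(fn.warp(interior) - (interior + 0.1))
        assert err.max() < 2.0 / 100

    def test_warp_monotone_on_grid(self):
        anchors = synthetic_anchors(lambda x: x**1.5)
        fn = compute_warp(anchors, AlignmentParameters())
        values = fn.warp(np.linspace(0, 1, 1000))
        assert np.all(np.diff(values) >= 0)
        assert 0.0 <= fn.warp(0.0) <= 1.0 and 0.0 <= fn.warp(1.0) <= 1.0

    def test_knots_strictly_increasing(self):
        anchors = synthetic_anchors(lambda x: x)
        fn = compute_warp(anchors, AlignmentParameters())
        assert np.all(np.diff(fn.knots[:, 0]) > 0)
        assert np.all(np.diff(fn.knots[:, 1]) > 0)

    def test_zero_anchors_rejected(self):
        with pytest.raises(AlignmentError):
            compute_warp([], AlignmentParameters())

    def test_self_alignment_scores_diagonal_band(self):
        anchors = synthetic_anchors(lambda x: x, sd_ppm=1.0)
        fn = compute_warp(anchors, AlignmentParameters())
        scores = fn.section_scores
        for i in range(scores.shape[0]):
            if scores[i].max() > 0:
                assert abs(int(np.argmax(scores[i])) - i) <= 1


class TestMassCorrection:
    def test_zero_deltas_zero_curve(self):
        anchors = synthetic_anchors(lambda x: x, sd_ppm=0.0)
        curve = compute_mass_correction(anchors)
        assert np.allclose(curve[:, 1], 0.0)

    def test_constant_offset_recovered(self):
        anchors = synthetic_anchors(lambda x: x, n=500, ppm=3.0, sd_ppm=0.5)
        fn = compute_warp(anchors, AlignmentParameters())
        residual = [a.delta_ppm - float(fn.ppm_shift(a.alignee_net)) for a in anchors]
        assert abs(np.median(residual)) < 0.5

    def test_symmetric_deltas_give_identity(self):
        # anchors symmetric about 0 ppm in every bin -> median 0 everywhere
        anchors = []
        for x in np.linspace(0.005, 0.995, 100):
            for sign in (-1.0, 1.0):
                anchors.append(AnchorMatch(float(x), float(x), sign * 2.0, 1000.0))
        curve = compute_mass_correction(anchors)
        assert np.allclose(curve[:, 1], 0.0)


class TestApplyAlignment:
    def test_identity_function_no_change(self):
        feats = compute_raw_net(features_at_scans(range(10, 1010, 100)))
        fn = la.AlignmentFunction.identity("ds", "ds")
        out = la.apply_alignment(feats, fn)
        assert [f.net for f in out] == pytest.approx([f.net for f in feats])
        assert [f.monoisotopic_mass for f in out] == [
            f.monoisotopic_mass for f in feats
        ]

    def test_order_preserved(self):
        feats = compute_raw_net(features_at_scans([5, 100, 340, 780, 1900]))
        anchors = synthetic_anchors(lambda x: x**1.3)
        fn = compute_warp(anchors, AlignmentParameters())
        out = la.apply_alignment(feats, fn)
        nets_in = [f.raw_net for f in out]
        nets_out = [f.net for f in out]
        assert np.all(np.diff(np.argsort(nets_in)) == np.diff(np.argsort(nets_out)))

    def test_originals_retained(self):
        feats = compute_raw_net(features_at_scans([10, 500, 900]))
        anchors = synthetic_anchors(lambda x: min(x + 0.05, 1.0), ppm=3.0)
        fn = compute_warp(anchors, AlignmentParameters())
        out = la.apply_alignment(feats, fn)
        for before, after in zip(feats, out):
            assert after.raw_net == before.raw_net
            assert after.raw_monoisotopic_mass == before.monoisotopic_mass
            assert after.monoisotopic_mass != before.monoisotopic_mass


class TestEndToEndWarpRecovery:
    def test_planted_warp_and_drift_recovered(self, tmp_path):
        """Three-segment elution distortion (max displacement 0.08) plus a
        +3 ppm mass drift must be corrected to <0.01 mean NET error and
        <0.5 ppm median mass error."""
        truth = la.make_ground_truth(
            n_analytes=200,
            n_datasets=2,
            seed=7,
            sd_ppm=0.5,
            sd_net=0.002,
            warp_max_displacement=0.08,
            warp_segments=3,
            ppm_offsets=3.0,
        )
        manifest = la.AnalysisManifest.from_yaml(
            la.generate_experiment(truth, tmp_path / "warp")
        )
        state = la.run_analysis(manifest, tmp_path / "out")
        masses = np.array([a.mass for a in truth.analytes])
        nets = np.array([a.base_net for a in truth.analytes])
        feats = state.lcms_features["ds01"]
        idx = [int(np.argmin(np.abs(masses - f.raw_monoisotopic_mass))) for f in feats]
        net_err = np.array([f.net - nets[i] for f, i in zip(feats, idx)])
        ppm_err = np.array(
            [1e6 * (f.monoisotopic_mass - masses[i]) / masses[i] for f, i in zip(feats, idx)]
        )
        raw_net_err = np.array([f.raw_net - nets[i] for f, i in zip(feats, idx)])
        raw_ppm_err = np.array(
            [1e6 * (f.raw_monoisotopic_mass - masses[i]) / masses[i]
             for f, i in zip(feats, idx)]
        )
        assert np.mean(np.abs(net_err)) < 0.01
        assert np.median(np.abs(ppm_err)) < 0.5
        # and alignment really improved on the raw data
        assert np.mean(np.abs(net_err)) < np.mean(np.abs(raw_net_err))
        assert np.median(np.abs(ppm_err)) < np.median(np.abs(raw_ppm_err))
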