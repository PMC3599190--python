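import numpy as np
import pytest

import lcmsalign as la


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A small but complete synthetic experiment run through the pipeline:
    30 analytes x 3 datasets, default noise, MS/MS spectra and AMT tags."""
    out = tmp_path_factory.mktemp("small_experiment")
    truth = la.make_ground_truth(n_analytes=30, n_datasets=3, seed=101)
    manifest_path = la.generate_experiment(truth, out / "data")
    manifest = la.AnalysisManifest.from_yaml(manifest_path)
    state = la.run_analysis(manifest, out / "results")
    return {
        "truth": truth,
        "manifest": manifest,
        "state": state,
        "data_dir": out / "data",
        "results_dir": out / "results",
    }


def make_ms_feature(
    dataset_id="ds",
    feature_id=0,
    scan=100,
    charge=2,
    monoisotopic_mass=1000.0,
    abundance=1e6,
    isotopic_fit=0.05,
):
    return la.MSFeature(
        dataset_id=dataset_id,
        feature_id=feature_id,
        scan=scan,
        charge=charge,
        mz=(monoisotopic_mass + charge * la.PROTON_MASS) / charge,
        monoisotopic_mass=monoisotopic_mass,
        abundance=abundance,
        isotopic_fit=isotopic_fit,
    )


def make_lcms_feature(
    dataset_id="ds",
    lcms_id=0,
    monoisotopic_mass=1000.0,
    net=0.5,
    scan=100,
    abundance=1e6,
    charges=(2,),
):
    return la.LCMSFeature(
        dataset_id=dataset_id,
        lcms_id=lcms_id,
        member_ids=[lcms_id],
        monoisotopic_mass=monoisotopic_mass,
        scan_start=scan,
        scan_end=scan,
        representative_scan=scan,
        abundance=abundance,
        charges=frozenset(charges),
        net=net,
        raw_net=net,
    )


def random_lcms_features(rng, n, datasets, mass_range=(400.0, 1600.0)):
    """Random aligned features, mass-dense enough to exercise partitions."""
    features = []
    for i in range(n):
        ds = datasets[int(rng.integers(len(datasets)))]
        features.append(
            make_lcms_feature(
                dataset_id=ds,
                lcms_id=i,
                monoisotopic_mass=float(rng.uniform(*mass_range)),
                net=float(rng.uniform(0, 1)),
                scan=int(rng.integers(1, 2000)),
                abundance=float(rng.uniform(1e4, 1e7)),
            )
        )
    return features
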