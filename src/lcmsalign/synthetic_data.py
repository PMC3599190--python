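"""Synthetic multi-dataset LC-MS experiments with known ground truth.

The generator plants a set of analytes (accurate mass, base NET, charge
states, per-dataset abundances, a fixed fragment template) and renders,
per dataset:

* an isos CSV in which each observed analyte becomes a short triangular
  elution profile of deisotoped MS-feature rows (3-10 scans, one row per
  planted charge state per scan), with mass jittered by N(0, sd_ppm)
  plus the dataset's systematic ppm offset, and scans placed by the
  dataset's monotone piecewise-linear NET distortion;
* an MGF of fragment spectra generated from the analyte's template at
  scans inside the elution profile;

plus an AMT-tag table listing every analyte at its base NET and a
machine-readable truth file for evaluators.

What this emulates: the statistical structure the alignment and
clustering steps assume — systematic elution/mass drift between runs on
top of random measurement error, with per-dataset dropout.  What it does
not: chimeric/overlapping isotopic envelopes, abundance-dependent mass
error, gradient dead time, or background chemical noise.

Identical seed implies byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import AMTTag, FeatureCluster, PROTON_MASS, TagMatch

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DatasetTruth:
    """Per-dataset systematic distortions."""

    dataset_id: str
    #: monotone piecewise-linear NET warp applied when rendering
    #: (true base NET -> observed NET), as (x, y) knots
    warp_knots: list[tuple[float, float]]
    #: constant mass offset (ppm) ...
    ppm_offset: float = 0.0
    #: ... plus a linear drift across NET: offset(net) = ppm_offset + ppm_drift*(net-0.5)
    ppm_drift: float = 0.0
    #: constant shift added to every rendered scan number
    scan_shift: int = 0

    def observed_net(self, base_net: float) -> float:
        xs = [k[0] for k in self.warp_knots]
        ys = [k[1] for k in self.warp_knots]
        return float(np.interp(base_net, xs, ys))

    def observed_ppm(self, base_net: float) -> float:
        return self.ppm_offset + self.ppm_drift * (base_net - 0.5)


@dataclass
class AnalyteTruth:
    analyte_id: int
    mass: float
    base_net: float
    charges: list[int]
    sequence: str
    #: per-dataset base abundance (before CV noise)
    abundances: dict[str, float] = field(default_factory=dict)
    #: per-dataset False when the analyte dropped out of that run
    observed: dict[str, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    analytes: list[AnalyteTruth]
    datasets: list[DatasetTruth]
    sd_ppm: float = 2.0
    sd_net: float = 0.005
    abundance_cv: float = 0.3
    dropout_rate: float = 0.0
    seed: int = 1
    n_scans: int = 2000
    fragment_peaks: int = 30
    spectra_per_analyte: int = 2

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]


def _identity_knots() -> list[tuple[float, float]]:
    return [(0.0, 0.0), (1.0, 1.0)]


def _random_warp_knots(
    rng: np.random.Generator, segments: int, max_displacement: float
) -> list[tuple[float, float]]:
    """Monotone piecewise-linear distortion with pinned endpoints."""
    if segments < 1 or max_displacement == 0.0:
        return _identity_knots()
    xs = np.linspace(0.0, 1.0, segments + 1)
    ys = xs.copy()
    for i in range(1, segments):
        lo = max(ys[i - 1] + 0.01, xs[i] - max_displacement)
        hi = xs[i] + max_displacement
        ys[i] = rng.uniform(lo, hi)
    ys = np.maximum.accumulate(ys)  # safety; strict by the +0.01 margin
    return list(zip(xs.tolist(), ys.tolist()))


def make_ground_truth(
    n_analytes: int = 200,
    n_datasets: int = 5,
    seed: int = 1,
    sd_ppm: float = 2.0,
    sd_net: float = 0.005,
    abundance_cv: float = 0.3,
    dropout_rate: float = 0.0,
    warp_segments: int = 3,
    warp_max_displacement: float = 0.0,
    ppm_offsets=None,
    scan_shifts=None,
    mass_range: tuple[float, float] = (500.0, 2500.0),
    net_range: tuple[float, float] = (0.02, 0.98),
    min_mass_gap: float = 0.05,
    n_scans: int = 2000,
) -> GroundTruth:
    """Plant an experiment.  The first dataset is the identity baseline.

    Masses are redrawn until every consecutive pair is at least
    ``min_mass_gap`` Dalton apart, so planted analytes are resolvable at
    the default ppm tolerances.
    """
    rng = np.random.default_rng(seed)
    masses = np.sort(rng.uniform(*mass_range, size=n_analytes))
    for _ in range(1000):
        gaps_ok = np.diff(masses) >= min_mass_gap
        if gaps_ok.all():
            break
        bad = np.flatnonzero(~gaps_ok) + 1
        masses[bad] = rng.uniform(*mass_range, size=bad.size)
        masses = np.sort(masses)
    else:
        raise RuntimeError("could not place analyte masses with the requested gap")

    nets = rng.uniform(*net_range, size=n_analytes)
    charge_menu = [[2], [2, 3], [1], [3]]
    charge_probs = [0.4, 0.3, 0.2, 0.1]

    datasets = []
    for d in range(n_datasets):
        ds_id = f"ds{d:02d}"
        if d == 0 or warp_max_displacement == 0.0:
            knots = _identity_knots()
        else:
            knots = _random_warp_knots(rng, warp_segments, warp_max_displacement)
        offset = 0.0
        if ppm_offsets is not None and d > 0:
            offset = float(ppm_offsets) if np.isscalar(ppm_offsets) else float(ppm_offsets[d])
        shift = 0
        if scan_shifts is not None:
            shift = int(scan_shifts[d])
        datasets.append(
            DatasetTruth(dataset_id=ds_id, warp_knots=knots, ppm_offset=offset,
                         scan_shift=shift)
        )

    analytes = []
    seen_sequences: set[str] = set()
    for a in range(n_analytes):
        while True:
            seq = "".join(rng.choice(list(_AMINO_ACIDS), size=int(rng.integers(10, 17))))
            if seq not in seen_sequences:
                seen_sequences.add(seq)
                break
        charges = charge_menu[int(rng.choice(len(charge_menu), p=charge_probs))]
        base_abundance = float(10 ** rng.uniform(5.0, 7.0))
        abundances = {}
        observed = {}
        for d in datasets:
            abundances[d.dataset_id] = base_abundance * float(
                rng.lognormal(0.0, abundance_cv)
            )
            observed[d.dataset_id] = bool(rng.uniform() >= dropout_rate)
        analytes.append(
            AnalyteTruth(
                analyte_id=a,
                mass=float(masses[a]),
                base_net=float(nets[a]),
                charges=list(charges),
                sequence=seq,
                abundances=abundances,
                observed=observed,
            )
        )
    return GroundTruth(
        analytes=analytes,
        datasets=datasets,
        sd_ppm=sd_ppm,
        sd_net=sd_net,
        abundance_cv=abundance_cv,
        dropout_rate=dropout_rate,
        seed=seed,
        n_scans=n_scans,
    )


def _fragment_template(truth: GroundTruth, analyte: AnalyteTruth) -> np.ndarray:
    """Fixed per-analyte pseudo-random peak set: identical across datasets
    (clusterable) and near-orthogonal across analytes."""
    rng = np.random.default_rng([truth.seed, 7919, analyte.analyte_id])
    mz = np.sort(rng.uniform(200.0, 1500.0, size=truth.fragment_peaks))
    intensity = rng.uniform(10.0, 100.0, size=truth.fragment_peaks)
    return np.column_stack([mz, intensity])


def generate_experiment(truth: GroundTruth, out_dir, overwrite: bool = False) -> Path:
    """Render the experiment; returns the manifest path."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest_datasets = []
    for d_index, ds in enumerate(truth.datasets):
        rng = np.random.default_rng([truth.seed, 104729, d_index])
        iso_rows = []  # (scan, charge, abundance, mz, fit, mono_mass)
        mgf_blocks = []
        for analyte in truth.analytes:
            if not analyte.observed[ds.dataset_id]:
                continue
            profile_len = int(rng.integers(3, 11))
            apex_offset = profile_len // 2
            obs_net = ds.observed_net(analyte.base_net) + float(rng.normal(0.0, truth.sd_net))
            obs_net = min(max(obs_net, 0.0), 1.0)
            apex_scan = 1 + int(round(obs_net * (truth.n_scans - 1))) + ds.scan_shift
            ppm_sys = ds.observed_ppm(analyte.base_net)
            abundance = analyte.abundances[ds.dataset_id]
            for k in range(profile_len):
                scan = apex_scan + (k - apex_offset)
                if scan < 1:
                    continue
                # triangular elution profile peaking at the apex
                weight = 1.0 - abs(k - apex_offset) / (apex_offset + 1.0)
                row_abundance = abundance * max(weight, 0.05)
                for z in analyte.charges:
                    ppm_err = ppm_sys + float(rng.normal(0.0, truth.sd_ppm))
                    mass = analyte.mass * (1.0 + ppm_err * 1e-6)
                    mz = (mass + z * PROTON_MASS) / z
                    fit = float(rng.uniform(0.0, 0.1))
                    iso_rows.append((scan, z, row_abundance / len(analyte.charges),
                                     mz, fit, mass))
            template = _fragment_template(truth, analyte)
            z0 = analyte.charges[0]
            for s in range(truth.spectra_per_analyte):
                scan = apex_scan + (s - truth.spectra_per_analyte // 2)
                if scan < 1 or abs(scan - apex_scan) > apex_offset:
                    continue
                precursor = (analyte.mass * (1.0 + ppm_sys * 1e-6) + z0 * PROTON_MASS) / z0
                mgf_blocks.append((scan, precursor, z0, template))

        iso_rows.sort(key=lambda r: (r[0], r[3], r[1]))
        isos_path = out_dir / f"{ds.dataset_id}.csv"
        with open(isos_path, "w", newline="") as fh:
            fh.write("scan_num,charge,abundance,mz,fit,monoisotopic_mw\n")
            for scan, z, abundance, mz, fit, mass in iso_rows:
                fh.write(f"{scan},{z},{abundance!r},{mz!r},{fit!r},{mass!r}\n")

        mgf_blocks.sort(key=lambda b: (b[0], b[1]))
        mgf_path = out_dir / f"{ds.dataset_id}.mgf"
        with open(mgf_path, "w") as fh:
            for scan, precursor, z, template in mgf_blocks:
                fh.write("BEGIN IONS\n")
                fh.write(f"TITLE={ds.dataset_id} scan={scan}\n")
                fh.write(f"PEPMASS={precursor!r}\n")
                fh.write(f"CHARGE={z}+\n")
                fh.write(f"SCANS={scan}\n")
                for mz, intensity in template:
                    fh.write(f"{float(mz)!r} {float(intensity)!r}\n")
                fh.write("END IONS\n")

        manifest_datasets.append(
            {
                "isos": isos_path.name,
                "spectra": mgf_path.name,
                "role": "baseline" if d_index == 0 else "alignee",
            }
        )

    tags_path = out_dir / "amt_tags.csv"
    with open(tags_path, "w", newline="") as fh:
        fh.write("sequence,monoisotopic_mass,net,observation_count\n")
        for analyte in truth.analytes:
            fh.write(
                f"{analyte.sequence},{analyte.mass!r},{analyte.base_net!r},{len(truth.datasets)}\n"
            )

    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth_to_dict(truth), indent=1, sort_keys=True))

    manifest = {
        "datasets": manifest_datasets,
        "amt_tags": tags_path.name,
        "alignment_mode": "database",
        "truth": truth_path.name,
    }
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def truth_to_dict(truth: GroundTruth) -> dict:
    return asdict(truth)


def truth_from_dict(data: dict) -> GroundTruth:
    datasets = [DatasetTruth(**{**d, "warp_knots": [tuple(k) for k in d["warp_knots"]]})
                for d in data["datasets"]]
    analytes = [AnalyteTruth(**a) for a in data["analytes"]]
    rest = {
        k: v for k, v in data.items() if k not in ("datasets", "analytes")
    }
    return GroundTruth(analytes=analytes, datasets=datasets, **rest)


def load_truth(path) -> GroundTruth:
    return truth_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """How well a pipeline run recovered the planted ground truth."""

    analyte_recall: float
    cluster_purity: float
    identification_accuracy: float
    n_analytes: int
    n_recovered: int
    n_clusters: int
    n_pure_clusters: int


def evaluate_recovery(
    truth: GroundTruth,
    clusters: list[FeatureCluster],
    matches: list[TagMatch] | None = None,
    tag_sequences: dict[str, str] | None = None,
    mass_tol_ppm: float = 10.0,
    net_tol: float = 0.03,
) -> RecoveryReport:
    """Score clusters (and optionally identifications) against the truth.

    * **recall**: fraction of planted analytes for which exactly one
      cluster centroid lies within *half* the gates of the planted
      (mass, NET) and that cluster has members from every non-dropped
      dataset;
    * **purity**: fraction of clusters whose members all attribute (full
      gates, nearest analyte) to one planted analyte;
    * **identification accuracy**: over recovered analytes, fraction
      whose top-uniqueness tag match is the planted tag (requires
      ``matches`` and ``tag_sequences``: tag_id -> peptide sequence).
    """
    if not clusters:
        raise ValueError("no clusters to evaluate; was the pipeline run?")
    planted_mass = np.array([a.mass for a in truth.analytes])
    planted_net = np.array([a.base_net for a in truth.analytes])

    # --- recall -----------------------------------------------------------
    centroid_mass = np.array([c.centroid_mass for c in clusters])
    centroid_net = np.array([c.centroid_net for c in clusters])
    recovered_cluster: dict[int, int] = {}  # analyte_id -> cluster index
    n_recovered = 0
    for a_idx, analyte in enumerate(truth.analytes):
        d_ppm = 1e6 * np.abs(centroid_mass - planted_mass[a_idx]) / planted_mass[a_idx]
        d_net = np.abs(centroid_net - planted_net[a_idx])
        candidates = np.flatnonzero((d_ppm <= mass_tol_ppm / 2) & (d_net <= net_tol / 2))
        if candidates.size != 1:
            continue
        c = clusters[int(candidates[0])]
        needed = {ds for ds, seen in analyte.observed.items() if seen}
        have = {m.dataset_id for m in c.members}
        if needed and needed <= have:
            n_recovered += 1
            recovered_cluster[analyte.analyte_id] = int(candidates[0])

    # --- purity -----------------------------------------------------------
    def attribute(mass: float, net: float) -> int | None:
        d_ppm = 1e6 * np.abs(planted_mass - mass) / planted_mass
        d_net = np.abs(planted_net - net)
        ok = np.flatnonzero((d_ppm <= mass_tol_ppm) & (d_net <= net_tol))
        if ok.size == 0:
            return None
        scores = (d_ppm[ok] / mass_tol_ppm) ** 2 + (d_net[ok] / net_tol) ** 2
        return int(ok[int(np.argmin(scores))])

    n_pure = 0
    for c in clusters:
        owners = {attribute(m.monoisotopic_mass, m.net) for m in c.members}
        if len(owners) == 1 and None not in owners:
            n_pure += 1

    # --- identification accuracy -----------------------------------------
    ident_accuracy = math.nan
    if matches is not None and tag_sequences is not None and recovered_cluster:
        by_cluster: dict[int, list[TagMatch]] = {}
        for m in matches:
            by_cluster.setdefault(m.cluster_id, []).append(m)
        n_correct = 0
        for analyte_id, c_idx in recovered_cluster.items():
            cluster_id = clusters[c_idx].cluster_id
            cluster_matches = by_cluster.get(cluster_id, [])
            if not cluster_matches:
                continue
            top = max(cluster_matches, key=lambda m: (m.uniqueness, m.stac))
            analyte = next(a for a in truth.analytes if a.analyte_id == analyte_id)
            if tag_sequences.get(top.tag_id) == analyte.sequence:
                n_correct += 1
        ident_accuracy = n_correct / len(recovered_cluster)

    return RecoveryReport(
        analyte_recall=n_recovered / len(truth.analytes),
        cluster_purity=n_pure / len(clusters),
        identification_accuracy=ident_accuracy,
        n_analytes=len(truth.analytes),
        n_recovered=n_recovered,
        n_clusters=len(clusters),
        n_pure_clusters=n_pure,
    )
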