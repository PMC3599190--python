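"""Full-analysis orchestration: load -> find features -> align ->
cluster -> score -> match -> spectral-cluster -> persist -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats
from .alignment import LCMSWarpAligner, compute_raw_net
from .cross_clustering import FeatureClusterer
from .feature_finding import find_lcms_features, link_spectra
from .models import AlignmentFunction
from .parameters import AnalysisParameters
from .peak_matching import match_clusters_to_tags
from .spectral_clustering import SpectralClusterer
from .store import AnalysisState, ResultsStore, persist_results

logger = logging.getLogger(__name__)


@dataclass
class DatasetEntry:
    isos: Path
    spectra: Path | None = None
    role: str = "alignee"  # "baseline" or "alignee"

    @property
    def dataset_id(self) -> str:
        return Path(self.isos).stem


@dataclass
class AnalysisManifest:
    """What to analyze: datasets, optional AMT table, mode, parameters."""

    datasets: list[DatasetEntry]
    amt_tags: Path | None = None
    alignment_mode: str = "dataset"  # "database" or "dataset"
    parameters: AnalysisParameters = field(default_factory=AnalysisParameters)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("manifest needs at least one dataset")
        if self.alignment_mode not in ("database", "dataset"):
            raise ValueError(f"unknown alignment mode {self.alignment_mode!r}")
        if self.alignment_mode == "database" and self.amt_tags is None:
            raise ValueError("database alignment mode requires an AMT tag table")
        baselines = [d for d in self.datasets if d.role == "baseline"]
        if self.alignment_mode == "dataset":
            if len(baselines) == 0:
                # default: first dataset in manifest order
                self.datasets[0].role = "baseline"
            elif len(baselines) > 1:
                raise ValueError("dataset-to-dataset mode needs exactly one baseline")

    @classmethod
    def from_yaml(cls, path, parameters: AnalysisParameters | None = None):
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        base = path.parent
        datasets = [
            DatasetEntry(
                isos=base / d["isos"],
                spectra=(base / d["spectra"]) if d.get("spectra") else None,
                role=d.get("role", "alignee"),
            )
            for d in data["datasets"]
        ]
        amt = (base / data["amt_tags"]) if data.get("amt_tags") else None
        params = parameters
        if params is None and data.get("parameters"):
            params = AnalysisParameters.from_file(base / data["parameters"])
        mode = data.get("alignment_mode", "database" if amt is not None else "dataset")
        return cls(
            datasets=datasets,
            amt_tags=amt,
            alignment_mode=mode,
            parameters=params or AnalysisParameters(),
        )


def run_analysis(manifest: AnalysisManifest, out_dir) -> AnalysisState:
    """Execute the whole workflow and write all result files to out_dir.

    Outputs: ``results.db3`` (SQLite), ``crosstab.csv``, one
    ``alignment_<dataset>.csv`` score matrix per aligned dataset, and a
    run log with per-stage counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = manifest.parameters
    state = AnalysisState(parameters=params)

    for entry in manifest.datasets:
        ds = entry.dataset_id
        state.dataset_info[ds] = {
            "isos_path": str(entry.isos),
            "spectra_path": str(entry.spectra) if entry.spectra else None,
            "role": entry.role,
        }
        ms = io_formats.read_isos_csv(entry.isos, params.loading_filters, dataset_id=ds)
        state.ms_features[ds] = ms
        lcms = find_lcms_features(ms, params.feature_finding)
        state.lcms_features[ds] = lcms
        logger.info("%s: %d MS features -> %d LC-MS features", ds, len(ms), len(lcms))
        if entry.spectra is not None:
            spectra = io_formats.read_spectra(entry.spectra, dataset_id=ds)
            state.spectra[ds] = spectra
            links = link_spectra(lcms, spectra, params.traceback)
            logger.info("%s: %d spectra, %d linked", ds, len(spectra), len(links))
        compute_raw_net(lcms)

    if manifest.amt_tags is not None:
        state.tags = io_formats.read_amt_tags(manifest.amt_tags)

    # alignment
    if manifest.alignment_mode == "database":
        baseline: object = state.tags
        baseline_ids = set()
    else:
        baseline_entry = next(d for d in manifest.datasets if d.role == "baseline")
        baseline_ids = {baseline_entry.dataset_id}
        baseline = state.lcms_features[baseline_entry.dataset_id]
    for ds in list(state.lcms_features):
        if ds in baseline_ids:
            state.alignments[ds] = AlignmentFunction.identity(
                ds, ds, params.alignment.num_sections
            )
            continue
        aligner = LCMSWarpAligner(
            num_sections=params.alignment.num_sections,
            max_expansion_factor=params.alignment.max_expansion_factor,
            match_mass_tolerance_ppm=params.alignment.match_mass_tolerance_ppm,
        )
        state.lcms_features[ds] = aligner.fit_transform(state.lcms_features[ds], baseline)
        state.alignments[ds] = aligner.alignment_
        io_formats.write_score_matrix(
            aligner.section_scores_, out_dir / f"alignment_{ds}.csv"
        )

    # cross-dataset clustering + scores
    all_features = [f for ds in state.lcms_features for f in state.lcms_features[ds]]
    clusterer = FeatureClusterer(
        method=params.clustering.method,
        mass_tolerance_ppm=params.clustering.mass_tolerance_ppm,
        net_tolerance=params.clustering.net_tolerance,
    )
    state.clusters = clusterer.fit(all_features).clusters_ if all_features else []
    logger.info("%d clusters from %d features", len(state.clusters), len(all_features))

    # AMT-tag matching
    if state.tags and state.clusters:
        state.matches, _ = match_clusters_to_tags(
            state.clusters, state.tags, params.matching
        )
        logger.info("%d tag matches", len(state.matches))

    # spectral clustering over feature-linked spectra
    state.spectral_clusters = []
    if state.spectra:
        linked_ids = {
            ds: {sid for f in feats for sid in f.spectrum_ids}
            for ds, feats in state.lcms_features.items()
        }
        all_spectra = [s for ds in sorted(state.spectra) for s in state.spectra[ds]]
        spectral = SpectralClusterer(
            bin_width=params.spectral.bin_width,
            top_k_peaks=params.spectral.top_k_peaks,
            similarity_threshold=params.spectral.similarity_threshold,
            precursor_mz_tolerance=params.traceback.precursor_mz_tolerance,
        )
        state.spectral_clusters = spectral.fit(all_spectra, linked_ids=linked_ids).clusters_
        logger.info("%d spectral clusters", len(state.spectral_clusters))

    persist_results(state, out_dir / "results.db3", overwrite=True)
    io_formats.write_crosstab(state.clusters, state.dataset_order, out_dir / "crosstab.csv")
    return state


@dataclass
class AnalysisSummary:
    feature_counts: dict[str, int]
    n_clusters: int
    n_non_singleton: int
    n_spanning_all: int
    n_unambiguous_matches: int

    def to_text(self) -> str:
        lines = ["LC-MS features per dataset:"]
        for ds, n in self.feature_counts.items():
            lines.append(f"  {ds}: {n}")
        lines += [
            f"clusters: {self.n_clusters}",
            f"non-singleton clusters: {self.n_non_singleton}",
            f"clusters spanning all datasets: {self.n_spanning_all}",
            f"unambiguous tag matches (uniqueness > 0.5): {self.n_unambiguous_matches}",
        ]
        return "\n".join(lines)


def summarize(results_path, histograms_dir=None) -> AnalysisSummary:
    """Summarize a persisted analysis; optionally export the tightness
    and ambiguity histograms as CSV."""
    with ResultsStore(results_path) as store:
        feature_counts = {
            ds: store.con.execute(
                "SELECT COUNT(*) FROM lcms_features WHERE dataset_id = ?", (ds,)
            ).fetchone()[0]
            for ds in store.dataset_ids()
        }
        n_datasets = len(feature_counts)
        n_clusters = store.table_count("clusters")
        n_non_singleton = store.con.execute(
            "SELECT COUNT(*) FROM clusters WHERE dataset_count >= 2"
        ).fetchone()[0]
        n_spanning = store.con.execute(
            "SELECT COUNT(*) FROM clusters WHERE dataset_count = ?", (n_datasets,)
        ).fetchone()[0]
        n_unambiguous = store.con.execute(
            "SELECT COUNT(DISTINCT cluster_id) FROM matches WHERE uniqueness > 0.5"
        ).fetchone()[0]
        if histograms_dir is not None:
            histograms_dir = Path(histograms_dir)
            histograms_dir.mkdir(parents=True, exist_ok=True)
            for column in ("tightness", "ambiguity"):
                values = [
                    r[0]
                    for r in store.con.execute(f"SELECT {column} FROM clusters")
                    if r[0] is not None and np.isfinite(r[0])
                ]
                counts, edges = np.histogram(values, bins=50) if values else (
                    np.zeros(50, int), np.linspace(0, 1, 51))
                with open(histograms_dir / f"{column}_histogram.csv", "w") as fh:
                    fh.write("bin_left,bin_right,count\n")
                    for left, right, count in zip(edges[:-1], edges[1:], counts):
                        fh.write(f"{left!r},{right!r},{int(count)}\n")
    return AnalysisSummary(
        feature_counts=feature_counts,
        n_clusters=n_clusters,
        n_non_singleton=n_non_singleton,
        n_spanning_all=n_spanning,
        n_unambiguous_matches=n_unambiguous,
    )
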