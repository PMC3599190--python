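"""Traceback: from feature clusters to the MS/MS spectra behind them.

The traceback answers "which fragmentation spectra were acquired on the
analyte this cross-dataset cluster represents?" by following
cluster -> member LC-MS features -> linked spectra, either over the
in-memory analysis state or over the persisted SQLite store (both routes
must agree; the tests assert it).  Selected clusters' spectra can be
exported as MGF for downstream identification (database search or
de novo sequencing).
"""

from __future__ import annotations

import math

from .io_formats import write_mgf
from .models import FeatureCluster, MSnSpectrum, TracebackRecord
from .store import AnalysisState, ResultsStore


def spectra_for_cluster(cluster_id: int, state: AnalysisState) -> list[TracebackRecord]:
    """All spectra linked to any member feature of the cluster."""
    by_id = {c.cluster_id: c for c in state.clusters}
    if cluster_id not in by_id:
        raise KeyError(f"unknown cluster id {cluster_id}")
    cluster = by_id[cluster_id]
    records = []
    for member in cluster.members:
        spectra = {s.spectrum_id: s for s in state.spectra.get(member.dataset_id, [])}
        for sid in sorted(member.spectrum_ids):
            s = spectra[sid]
            records.append(
                TracebackRecord(
                    cluster_id=cluster_id,
                    dataset_id=member.dataset_id,
                    lcms_id=member.lcms_id,
                    spectrum_id=sid,
                    scan=s.scan,
                    precursor_mz=s.precursor_mz,
                )
            )
    records.sort(key=lambda r: (r.dataset_id, r.lcms_id, r.spectrum_id))
    return records


def spectra_for_cluster_sql(cluster_id: int, store: ResultsStore) -> list[TracebackRecord]:
    """Same traceback, answered by the SQLite store."""
    return [
        TracebackRecord(
            cluster_id=row["cluster_id"],
            dataset_id=row["dataset_id"],
            lcms_id=row["lcms_id"],
            spectrum_id=row["spectrum_id"],
            scan=row["scan"],
            precursor_mz=row["precursor_mz"],
        )
        for row in store.spectra_for_cluster(cluster_id)
    ]


def export_cluster_spectra(cluster_ids: list[int], state: AnalysisState, path) -> int:
    """Write the traced-back spectra of the given clusters to an MGF.

    The TITLE of each block encodes (cluster id, dataset id, scan) so hits
    from downstream search tools map straight back to clusters.  Returns
    the number of blocks written.
    """
    spectra: list[MSnSpectrum] = []
    titles: list[str] = []
    for cid in cluster_ids:
        for record in spectra_for_cluster(cid, state):
            source = {
                s.spectrum_id: s for s in state.spectra[record.dataset_id]
            }[record.spectrum_id]
            spectra.append(source)
            titles.append(
                f"cluster={record.cluster_id} dataset={record.dataset_id} "
                f"scan={record.scan}"
            )
    write_mgf(spectra, path, titles=titles)
    return len(spectra)


def select_target_clusters(
    clusters: list[FeatureCluster],
    min_datasets: int = 1,
    max_tightness: float = math.inf,
    min_ambiguity: float = 0.0,
    unidentified_only: bool = False,
    matches=None,
) -> list[int]:
    """Filter clusters worth follow-up (e.g. targeted re-analysis).

    Keeps clusters seen in at least ``min_datasets`` datasets, with
    tightness at most ``max_tightness`` and ambiguity at least
    ``min_ambiguity``.  With ``unidentified_only`` a cluster is dropped
    when any of its tag matches is unambiguous (uniqueness > 0.5).
    """
    identified: set[int] = set()
    if unidentified_only:
        for m in matches or []:
            if m.uniqueness is not None and m.uniqueness > 0.5:
                identified.add(m.cluster_id)
    selected = []
    for c in clusters:
        if c.dataset_count < min_datasets:
            continue
        if not (c.tightness <= max_tightness):
            continue
        if not (c.ambiguity >= min_ambiguity):
            continue
        if unidentified_only and c.cluster_id in identified:
            continue
        selected.append(c.cluster_id)
    return selected
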