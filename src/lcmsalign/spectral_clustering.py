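"""Cross-dataset MS/MS spectral clustering and the delta-scan diagnostic.

Only spectra already linked to LC-MS features are clustered — a spectrum
with a supporting elution profile is far less likely to be transient
noise.  Each spectrum is reduced to its ``top_k_peaks`` most intense
peaks, intensities square-rooted (damping the dominant ions), binned on
an m/z grid, and scaled to unit norm; similarity is then the normalized
dot product (a cosine on nonnegative unit vectors, so it lies in [0, 1]).

Clustering is greedy agglomeration: candidate pairs are restricted to
spectra with close precursor m/z, merged in descending similarity order,
and a merge stands only if every member of the merged cluster keeps a
similarity of at least ``similarity_threshold`` to the cluster's
representative (its highest-total-intensity member).

The *delta-scan residual* diagnostic takes, per cluster, all scan
differences between member pairs drawn one from each of two named
datasets.  For technical replicates the residuals sit near zero; a
systematic elution shift between runs appears as a shifted residual
median, and diverging samples show a wide, incoherent spread.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from sklearn.base import BaseEstimator

from .models import MSnSpectrum, ProcessedSpectrum, SpectralCluster
from .parameters import SpectralParameters


def preprocess_spectrum(
    s: MSnSpectrum, bin_width: float = 1.0005, top_k_peaks: int = 50
) -> ProcessedSpectrum:
    """Reduce a spectrum to a unit-norm binned top-k peak vector."""
    if s.peaks.shape[0] == 0:
        raise ValueError("cannot preprocess a spectrum with no peaks")
    peaks = s.peaks
    if peaks.shape[0] > top_k_peaks:
        # ties on intensity broken toward lower m/z for determinism
        order = np.lexsort((peaks[:, 0], -peaks[:, 1]))[:top_k_peaks]
        peaks = peaks[order]
    bins: dict[int, float] = {}
    for mz, intensity in peaks:
        b = int(mz // bin_width)
        bins[b] = bins.get(b, 0.0) + math.sqrt(max(intensity, 0.0))
    norm = math.sqrt(sum(v * v for v in bins.values()))
    if norm == 0.0:
        # all-zero intensities: fall back to flat weights over the bins
        bins = {b: 1.0 for b in bins}
        norm = math.sqrt(len(bins))
    bins = {b: v / norm for b, v in bins.items()}
    return ProcessedSpectrum(
        dataset_id=s.dataset_id,
        spectrum_id=s.spectrum_id,
        scan=s.scan,
        precursor_mz=s.precursor_mz,
        bins=bins,
        total_intensity=float(np.sum(s.peaks[:, 1])),
    )


def spectral_similarity(a: ProcessedSpectrum, b: ProcessedSpectrum) -> float:
    """Normalized dot product over shared bins; in [0, 1], 1 on identity."""
    if len(a.bins) > len(b.bins):
        a, b = b, a
    value = sum(w * b.bins.get(k, 0.0) for k, w in a.bins.items())
    return min(value, 1.0)


def _representative(members: list[ProcessedSpectrum]) -> ProcessedSpectrum:
    return min(members, key=lambda p: (-p.total_intensity, p.dataset_id, p.spectrum_id))


def cluster_spectra(
    spectra: list[MSnSpectrum],
    params: SpectralParameters | None = None,
    precursor_mz_tolerance: float = 0.05,
    linked_ids: dict[str, set[int]] | None = None,
) -> list[SpectralCluster]:
    """Greedy agglomerative clustering of feature-linked MS/MS spectra.

    ``linked_ids`` maps dataset id to the spectrum ids that are linked to
    LC-MS features; unlinked spectra are excluded (pass ``None`` to keep
    all, e.g. for unit tests on already-gated input).
    """
    params = params or SpectralParameters()
    pool = [
        s
        for s in spectra
        if linked_ids is None
        or s.spectrum_id in linked_ids.get(s.dataset_id, set())
    ]
    processed = [
        preprocess_spectrum(s, params.bin_width, params.top_k_peaks)
        for s in pool
        if s.peaks.shape[0] > 0
    ]
    n = len(processed)
    # candidate pairs: precursor m/z within tolerance (sorted window)
    order = sorted(range(n), key=lambda i: processed[i].precursor_mz)
    pairs: list[tuple[float, int, int]] = []
    for ai in range(n):
        i = order[ai]
        for bi in range(ai + 1, n):
            j = order[bi]
            if processed[j].precursor_mz - processed[i].precursor_mz > precursor_mz_tolerance:
                break
            sim = spectral_similarity(processed[i], processed[j])
            if sim >= params.similarity_threshold:
                pairs.append((sim, min(i, j), max(i, j)))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    cluster_of = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for sim, i, j in pairs:
        ci, cj = cluster_of[i], cluster_of[j]
        if ci == cj:
            continue
        merged = members[ci] + members[cj]
        rep = _representative([processed[k] for k in merged])
        if all(
            spectral_similarity(processed[k], rep) >= params.similarity_threshold
            for k in merged
        ):
            keep, drop = min(ci, cj), max(ci, cj)
            members[keep] = members[keep] + members[drop]
            for k in members[drop]:
                cluster_of[k] = keep
            del members[drop]

    clusters = []
    for new_id, key in enumerate(sorted(members)):
        mem = [processed[k] for k in sorted(members[key])]
        clusters.append(
            SpectralCluster(
                cluster_id=new_id,
                members=mem,
                representative=_representative(mem),
            )
        )
    return clusters


def delta_scan_residuals(
    clusters: list[SpectralCluster], dataset_a: str, dataset_b: str
) -> list[tuple[int, int]]:
    """(cluster_index, scan_a - scan_b) rows for every cross-dataset member
    pair; clusters lacking either dataset contribute no rows."""
    rows: list[tuple[int, int]] = []
    for index, c in enumerate(clusters):
        from_a = [m for m in c.members if m.dataset_id == dataset_a]
        from_b = [m for m in c.members if m.dataset_id == dataset_b]
        for ma, mb in itertools.product(from_a, from_b):
            rows.append((index, ma.scan - mb.scan))
    return rows


class SpectralClusterer(BaseEstimator):
    """Estimator facade over :func:`cluster_spectra`.

    After ``fit``: ``clusters_`` and ``labels_`` (cluster id per kept
    spectrum, in input order; -1 for excluded/empty spectra).
    """

    def __init__(
        self,
        bin_width: float = 1.0005,
        top_k_peaks: int = 50,
        similarity_threshold: float = 0.7,
        precursor_mz_tolerance: float = 0.05,
    ):
        self.bin_width = bin_width
        self.top_k_peaks = top_k_peaks
        self.similarity_threshold = similarity_threshold
        self.precursor_mz_tolerance = precursor_mz_tolerance

    def fit(self, X: list[MSnSpectrum], y=None, linked_ids=None):
        params = SpectralParameters(
            bin_width=self.bin_width,
            top_k_peaks=self.top_k_peaks,
            similarity_threshold=self.similarity_threshold,
        )
        self.clusters_ = cluster_spectra(
            list(X), params, self.precursor_mz_tolerance, linked_ids
        )
        key_of = {}
        for c in self.clusters_:
            for m in c.members:
                key_of[(m.dataset_id, m.spectrum_id)] = c.cluster_id
        self.labels_ = np.array(
            [key_of.get((s.dataset_id, s.spectrum_id), -1) for s in X]
        )
        return self

    def fit_predict(self, X, y=None, linked_ids=None) -> np.ndarray:
        return self.fit(X, linked_ids=linked_ids).labels_
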