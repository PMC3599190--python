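"""Group MS features into LC-MS features and link MS/MS spectra to them.

An LC-MS feature is built by single-linkage clustering of MS features
under a weighted L2 distance over mass (ppm), elution time (scans) and
log-intensity, with hard join gates on the mass and scan axes.  Because
a pair may join only when it satisfies both gates, the final grouping is
exactly the set of connected components of the gate graph; the merge
order (ascending distance, ties by feature-id pair) only fixes labels.

Spectra link to features through the precursor m/z reconstructed from the
feature's neutral mass at each observed charge:  m/z = (M + z*p)/z with p
the proton mass.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from .models import LCMSFeature, MSFeature, MSnSpectrum, PROTON_MASS, ppm_between
from .parameters import FeatureFindingParameters, TracebackParameters


def ms_feature_distance(
    a: MSFeature,
    b: MSFeature,
    params: FeatureFindingParameters,
) -> float:
    """Weighted L2 distance between two MS features.

    Each axis is normalized by its tolerance so that a unit distance on an
    axis means "exactly at tolerance": sqrt(w_m*(dppm/tol_ppm)^2 +
    w_t*(dscan/gap_tol)^2 + w_i*dlog10(abundance)^2).
    """
    d_ppm = ppm_between(a.monoisotopic_mass, b.monoisotopic_mass)
    d_scan = abs(a.scan - b.scan)
    total = (
        params.w_mass * (d_ppm / params.mass_tolerance_ppm) ** 2
        + params.w_time * (d_scan / max(params.scan_gap_tolerance, 1)) ** 2
    )
    if params.w_intensity > 0:
        log_a = math.log10(a.abundance) if a.abundance > 0 else 0.0
        log_b = math.log10(b.abundance) if b.abundance > 0 else 0.0
        total += params.w_intensity * (log_a - log_b) ** 2
    return math.sqrt(total)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # smaller root wins, keeping labels independent of merge order
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj


class LCMSFeatureFinder(BaseEstimator):
    """Single-linkage grouping of MS features into LC-MS features.

    Parameters
    ----------
    mass_tolerance_ppm : float
        Two MS features may join only if their masses differ by at most
        this many ppm.
    scan_gap_tolerance : int
        ... and their scans by at most this many scans.
    min_feature_length : int
        Groups with fewer members are discarded.
    w_mass, w_time, w_intensity : float
        Axis weights of the distance (reported, not gating).

    Attributes
    ----------
    features_ : list[LCMSFeature]
        The LC-MS features, sorted by (monoisotopic mass, scan_start).
    labels_ : ndarray of int
        Per-input-feature index into ``features_``; -1 for members of
        discarded (too short) groups.
    n_discarded_ : int
        Number of MS features in discarded groups.
    """

    def __init__(
        self,
        mass_tolerance_ppm: float = 10.0,
        scan_gap_tolerance: int = 5,
        min_feature_length: int = 1,
        w_mass: float = 1.0,
        w_time: float = 1.0,
        w_intensity: float = 0.0,
    ):
        self.mass_tolerance_ppm = mass_tolerance_ppm
        self.scan_gap_tolerance = scan_gap_tolerance
        self.min_feature_length = min_feature_length
        self.w_mass = w_mass
        self.w_time = w_time
        self.w_intensity = w_intensity

    def fit(self, X: list[MSFeature], y=None):
        features = list(X)
        if features and len({f.dataset_id for f in features}) != 1:
            raise ValueError("feature finding operates on a single dataset at a time")
        n = len(features)
        # deterministic processing order regardless of input row order
        order = sorted(range(n), key=lambda i: (features[i].monoisotopic_mass,
                                                features[i].scan,
                                                features[i].feature_id))
        masses = np.array([features[i].monoisotopic_mass for i in order])
        scans = np.array([features[i].scan for i in order])

        uf = _UnionFind(n)
        tol = self.mass_tolerance_ppm
        for a in range(n):
            m_a = masses[a]
            for b in range(a + 1, n):
                # sorted masses: once the pairwise ppm gap exceeds tol it
                # only grows, so the window can close
                if 1e6 * (masses[b] - m_a) / ((masses[b] + m_a) / 2.0) > tol:
                    break
                if abs(scans[b] - scans[a]) <= self.scan_gap_tolerance:
                    uf.union(order[a], order[b])

        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), []).append(i)

        built = []
        for member_idx in groups.values():
            if len(member_idx) < self.min_feature_length:
                built.append((None, member_idx))
                continue
            built.append((self._materialize(features, member_idx), member_idx))

        kept = [(f, idx) for f, idx in built if f is not None]
        kept.sort(key=lambda t: (t[0].monoisotopic_mass, t[0].scan_start, t[0].lcms_id))

        labels = np.full(n, -1, dtype=int)
        features_out = []
        for new_id, (f, idx) in enumerate(kept):
            f.lcms_id = new_id
            features_out.append(f)
            labels[idx] = new_id

        self.features_ = features_out
        self.labels_ = labels
        self.n_discarded_ = int(np.sum(labels == -1))
        return self

    def fit_predict(self, X: list[MSFeature], y=None) -> np.ndarray:
        return self.fit(X).labels_

    @staticmethod
    def _materialize(features: list[MSFeature], member_idx: list[int]) -> LCMSFeature:
        members = [features[i] for i in member_idx]
        # representative scan = scan of the most abundant member (ties ->
        # smallest scan)
        rep = min(members, key=lambda f: (-f.abundance, f.scan))
        return LCMSFeature(
            dataset_id=members[0].dataset_id,
            lcms_id=-1,
            member_ids=sorted(f.feature_id for f in members),
            monoisotopic_mass=float(np.median([f.monoisotopic_mass for f in members])),
            scan_start=min(f.scan for f in members),
            scan_end=max(f.scan for f in members),
            representative_scan=rep.scan,
            abundance=float(sum(f.abundance for f in members)),
            charges=frozenset(f.charge for f in members),
        )


def find_lcms_features(
    features: list[MSFeature],
    params: FeatureFindingParameters | None = None,
) -> list[LCMSFeature]:
    """Functional wrapper over :class:`LCMSFeatureFinder`."""
    params = params or FeatureFindingParameters()
    finder = LCMSFeatureFinder(
        mass_tolerance_ppm=params.mass_tolerance_ppm,
        scan_gap_tolerance=params.scan_gap_tolerance,
        min_feature_length=params.min_feature_length,
        w_mass=params.w_mass,
        w_time=params.w_time,
        w_intensity=params.w_intensity,
    )
    return finder.fit(features).features_


def link_spectra(
    lcms: list[LCMSFeature],
    spectra: list[MSnSpectrum],
    params: TracebackParameters | None = None,
) -> dict[int, list[int]]:
    """Link MS/MS spectra to LC-MS features; returns the spectrum-side map.

    A spectrum links to a feature when its scan falls inside the feature's
    scan span extended by ``scan_window`` and its precursor m/z is within
    ``precursor_mz_tolerance`` (Th) of the feature's m/z reconstructed at
    any observed charge.  A spectrum may link to several features.  Links
    are recorded on both sides: on each feature's ``spectrum_ids`` and in
    the returned ``{spectrum_id: [lcms_id, ...]}`` mapping.
    """
    params = params or TracebackParameters()
    spectrum_links: dict[int, list[int]] = {}
    if not lcms or not spectra:
        return spectrum_links
    spec_scans = np.array([s.scan for s in spectra])
    order = np.argsort(spec_scans, kind="stable")
    spec_scans = spec_scans[order]
    for f in lcms:
        lo = np.searchsorted(spec_scans, f.scan_start - params.scan_window, side="left")
        hi = np.searchsorted(spec_scans, f.scan_end + params.scan_window, side="right")
        if lo >= hi:
            continue
        candidate_mz = [
            (f.monoisotopic_mass + z * PROTON_MASS) / z for z in sorted(f.charges)
        ]
        for k in range(lo, hi):
            s = spectra[int(order[k])]
            err = min(abs(s.precursor_mz - mz) for mz in candidate_mz)
            if err <= params.precursor_mz_tolerance:
                if s.spectrum_id not in f.spectrum_ids:
                    f.spectrum_ids.append(s.spectrum_id)
                    spectrum_links.setdefault(s.spectrum_id, []).append(f.lcms_id)
    return spectrum_links
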