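"""Independent brute-force oracles the fast implementations are checked
against.  Clustering oracles agglomerate over a dense pairwise distance
matrix — repeatedly merging the two groups containing the globally
closest gate-satisfying cross pair — with none of the sorting/windowing
or union-find machinery of the production code."""

from __future__ import annotations

import itertools

import numpy as np


def _agglomerate(dist: np.ndarray, allowed: np.ndarray) -> set[frozenset]:
    """Ascending-distance agglomeration over gate-satisfying pairs."""
    n = dist.shape[0]
    labels = list(range(n))
    pairs = sorted(
        ((dist[i, j], i, j) for i, j in itertools.combinations(range(n), 2) if allowed[i, j]),
    )
    for _, i, j in pairs:
        li, lj = labels[i], labels[j]
        if li != lj:
            keep, drop = min(li, lj), max(li, lj)
            labels = [keep if l == drop else l for l in labels]
    groups: dict[int, set[int]] = {}
    for idx, l in enumerate(labels):
        groups.setdefault(l, set()).add(idx)
    return {frozenset(g) for g in groups.values()}


def naive_single_linkage_ms(features, params) -> set[frozenset]:
    """Gated single linkage over MS features; returns feature-id groups."""
    n = len(features)
    mass = np.array([f.monoisotopic_mass for f in features])
    scan = np.array([f.scan for f in features], dtype=float)
    d_ppm = 1e6 * np.abs(mass[:, None] - mass[None, :]) / ((mass[:, None] + mass[None, :]) / 2)
    d_scan = np.abs(scan[:, None] - scan[None, :])
    allowed = (d_ppm <= params.mass_tolerance_ppm) & (d_scan <= params.scan_gap_tolerance)
    dist = np.sqrt(
        params.w_mass * (d_ppm / params.mass_tolerance_ppm) ** 2
        + params.w_time * (d_scan / max(params.scan_gap_tolerance, 1)) ** 2
    )
    groups = _agglomerate(dist, allowed)
    return {frozenset(features[i].feature_id for i in g) for g in groups}


def naive_single_linkage_lcms(features, mass_tol_ppm, net_tol) -> set[frozenset]:
    """Gated single linkage over aligned LC-MS features in (mass, NET)."""
    mass = np.array([f.monoisotopic_mass for f in features])
    net = np.array([f.net for f in features])
    d_ppm = 1e6 * np.abs(mass[:, None] - mass[None, :]) / ((mass[:, None] + mass[None, :]) / 2)
    d_net = np.abs(net[:, None] - net[None, :])
    allowed = (d_ppm <= mass_tol_ppm) & (d_net <= net_tol)
    dist = np.sqrt((d_ppm / mass_tol_ppm) ** 2 + (d_net / net_tol) ** 2)
    return _agglomerate(dist, allowed)


def brute_force_anchor_pairs(alignee, baseline_coords, mass_tol_ppm):
    """Double loop over all (feature, baseline entry) candidate pairs."""
    pairs = []
    for fi, f in enumerate(alignee):
        for bi, (mass, _net) in enumerate(baseline_coords):
            delta = 1e6 * (f.monoisotopic_mass - mass) / mass
            if abs(delta) <= mass_tol_ppm:
                pairs.append((fi, bi))
    return pairs


def brute_force_range_query(clusters, tags, mass_tol_ppm, net_tol):
    pairs = []
    for c in clusters:
        for t in tags:
            d_ppm = 1e6 * (c.centroid_mass - t.monoisotopic_mass) / t.monoisotopic_mass
            d_net = c.centroid_net - t.net
            if abs(d_ppm) <= mass_tol_ppm and abs(d_net) <= net_tol:
                pairs.append((c.cluster_id, t.tag_id))
    return pairs


def naive_spectral_clustering(processed, threshold, precursor_tol) -> set[frozenset]:
    """Greedy agglomeration, descending similarity, representative gate —
    computed over the full similarity matrix with no windowing."""
    from lcmsalign.spectral_clustering import _representative, spectral_similarity

    n = len(processed)
    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        if abs(processed[i].precursor_mz - processed[j].precursor_mz) > precursor_tol:
            continue
        sim = spectral_similarity(processed[i], processed[j])
        if sim >= threshold:
            pairs.append((sim, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    cluster_of = list(range(n))
    members = {i: [i] for i in range(n)}
    for _, i, j in pairs:
        ci, cj = cluster_of[i], cluster_of[j]
        if ci == cj:
            continue
        merged = members[ci] + members[cj]
        rep = _representative([processed[k] for k in merged])
        if all(spectral_similarity(processed[k], rep) >= threshold for k in merged):
            keep, drop = min(ci, cj), max(ci, cj)
            members[keep] += members[drop]
            for k in members[drop]:
                cluster_of[k] = keep
            del members[drop]
    return {frozenset(v) for v in members.values()}
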