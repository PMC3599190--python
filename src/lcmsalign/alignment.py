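"""Piecewise-linear NET warping and mass recalibration.

Systematic elution drift between runs (or between a run and a reference
AMT-tag database) is corrected by a monotone piecewise-linear warp of the
alignee's normalized elution time onto the baseline's, estimated by
dynamic programming over a grid of NET sections:

1. candidate *anchors* are all (alignee feature, baseline entry) pairs
   whose masses agree within a ppm tolerance — most are correct because
   accurate masses are near-unique, and wrong ones are down-weighted;
2. each anchor contributes a Gaussian mass-agreement score
   exp(-(dppm/sigma)^2 / 2) to the cell (alignee section, baseline
   section) containing its NET pair, giving the *section-score matrix*
   (the data behind alignment heat maps);
3. a DP selects the maximum-score monotone chain of section pairs; steps
   of up to ``max_expansion_factor`` sections on either axis allow local
   stretching or compression of the elution axis.  Chain cells become the
   warp's knots.

Mass drift is corrected separately: anchors are binned by alignee NET and
the per-bin median delta-ppm (robust to false anchors) is interpolated
into a piecewise-linear ppm-shift curve, which is subtracted from every
feature mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator

from .models import AMTTag, AlignmentFunction, AnchorMatch, LCMSFeature
from .parameters import AlignmentParameters

logger = logging.getLogger(__name__)


class AlignmentError(RuntimeError):
    """Alignment could not be computed (typically: no anchor pairs)."""


def compute_raw_net(features: list[LCMSFeature]) -> list[LCMSFeature]:
    """Populate raw NET by min-max scaling of representative scans.

    net = (scan - scan_min) / (scan_max - scan_min) over the dataset's
    representative scans; order-preserving and affine-invariant in scan.
    With all features at a single scan every NET is set to 0.5 (warned).
    """
    if not features:
        return features
    scans = np.array([f.representative_scan for f in features], dtype=float)
    lo, hi = scans.min(), scans.max()
    if hi == lo:
        logger.warning("all features at one scan; NET set to 0.5 for all")
        nets = np.full(len(features), 0.5)
    else:
        nets = (scans - lo) / (hi - lo)
    for f, net in zip(features, nets):
        f.raw_net = float(net)
        f.net = float(net)
    return features


def _baseline_coordinates(baseline) -> tuple[np.ndarray, np.ndarray]:
    """(mass, net) arrays from either LC-MS features or AMT tags."""
    if not baseline:
        return np.empty(0), np.empty(0)
    first = baseline[0]
    if isinstance(first, AMTTag):
        return (
            np.array([t.monoisotopic_mass for t in baseline]),
            np.array([t.net for t in baseline]),
        )
    return (
        np.array([f.monoisotopic_mass for f in baseline]),
        np.array([f.net for f in baseline]),
    )


def find_anchor_matches(
    alignee: list[LCMSFeature],
    baseline,
    mass_tol_ppm: float,
) -> list[AnchorMatch]:
    """All (alignee, baseline) pairs within the ppm tolerance.

    ``baseline`` may be a list of LC-MS features (dataset-to-dataset mode)
    or of AMT tags (database mode).  Raises :class:`AlignmentError` when
    no pair exists.
    """
    base_mass, base_net = _baseline_coordinates(list(baseline))
    order = np.argsort(base_mass, kind="stable")
    base_mass, base_net = base_mass[order], base_net[order]
    anchors: list[AnchorMatch] = []
    for f in alignee:
        m = f.monoisotopic_mass
        half_width = m * mass_tol_ppm * 1e-6
        lo = np.searchsorted(base_mass, m - half_width * 1.001, side="left")
        hi = np.searchsorted(base_mass, m + half_width * 1.001, side="right")
        for j in range(int(lo), int(hi)):
            delta_ppm = 1e6 * (m - base_mass[j]) / base_mass[j]
            if abs(delta_ppm) <= mass_tol_ppm:
                anchors.append(
                    AnchorMatch(
                        alignee_net=f.net,
                        baseline_net=float(base_net[j]),
                        delta_ppm=float(delta_ppm),
                        alignee_mass=m,
                    )
                )
    if not anchors:
        raise AlignmentError(
            "no anchor pairs within the mass tolerance; the mass ranges may "
            "be disjoint — try a larger match_mass_tolerance_ppm"
        )
    return anchors


def _section_scores(anchors: list[AnchorMatch], num_sections: int, sigma_ppm: float) -> np.ndarray:
    scores = np.zeros((num_sections, num_sections))
    for a in anchors:
        i = min(int(a.alignee_net * num_sections), num_sections - 1)
        j = min(int(a.baseline_net * num_sections), num_sections - 1)
        scores[i, j] += math.exp(-0.5 * (a.delta_ppm / sigma_ppm) ** 2)
    return scores


def _best_chain(scores: np.ndarray, max_step: int) -> list[tuple[int, int]]:
    """Maximum-score strictly monotone chain of cells with per-axis steps
    in 1..max_step (dynamic programming, O(N^2 * max_step^2))."""
    n = scores.shape[0]
    f = np.copy(scores)
    back = np.full((n, n, 2), -1, dtype=int)
    for i in range(n):
        for j in range(n):
            best = 0.0
            bi = bj = -1
            for di in range(1, max_step + 1):
                pi = i - di
                if pi < 0:
                    break
                for dj in range(1, max_step + 1):
                    pj = j - dj
                    if pj < 0:
                        break
                    if f[pi, pj] > best:
                        best = f[pi, pj]
                        bi, bj = pi, pj
            f[i, j] = scores[i, j] + best
            back[i, j] = (bi, bj)
    end = np.unravel_index(int(np.argmax(f)), f.shape)
    chain = []
    i, j = int(end[0]), int(end[1])
    while i >= 0:
        chain.append((i, j))
        i, j = int(back[i, j, 0]), int(back[i, j, 1])
    chain.reverse()
    return chain


def compute_warp(
    anchors: list[AnchorMatch],
    params: AlignmentParameters | None = None,
    dataset_id: str = "",
    baseline_id: str = "",
) -> AlignmentFunction:
    """Estimate the NET warp and mass-correction curve from anchors."""
    if not anchors:
        raise AlignmentError("cannot compute a warp from zero anchors")
    params = params or AlignmentParameters()
    n = params.num_sections
    sigma_ppm = params.match_mass_tolerance_ppm / 2.0
    scores = _section_scores(anchors, n, sigma_ppm)
    chain = _best_chain(scores, params.max_expansion_factor)

    # knots = Gaussian-weighted anchor centroids of the chain's cells
    # (not the geometric cell centers: with sparse anchors that would
    # bias the warp by up to half a section); chain cells that merely
    # bridge empty regions contribute no knot
    width = 1.0 / n
    cell_of: dict[tuple[int, int], list[AnchorMatch]] = {}
    for a in anchors:
        i = min(int(a.alignee_net * n), n - 1)
        j = min(int(a.baseline_net * n), n - 1)
        cell_of.setdefault((i, j), []).append(a)
    knot_rows = []
    for cell in chain:
        cell_anchors = cell_of.get(cell)
        if not cell_anchors:
            continue
        w = np.array([math.exp(-0.5 * (a.delta_ppm / sigma_ppm) ** 2)
                      for a in cell_anchors])
        if w.sum() <= 0:
            w = np.ones_like(w)
        ax = np.array([a.alignee_net for a in cell_anchors])
        bx = np.array([a.baseline_net for a in cell_anchors])
        knot_rows.append([float((w * ax).sum() / w.sum()),
                          float((w * bx).sum() / w.sum())])
    knots = np.array(knot_rows)
    if len(knots) == 1:  # degenerate: all anchors in one cell
        knots = np.vstack([knots - width, knots + width])
    knots = np.clip(knots, 0.0, 1.0)
    # the chain is strictly monotone by section, but centroid ties can
    # appear after clipping at the domain edges; enforce strictness
    strict = [0]
    for k in range(1, len(knots)):
        if knots[k, 0] > knots[strict[-1], 0] and knots[k, 1] > knots[strict[-1], 1]:
            strict.append(k)
    knots = knots[strict]

    fn = AlignmentFunction(
        dataset_id=dataset_id,
        baseline_id=baseline_id,
        knots=knots,
        mass_correction=np.array([[0.0, 0.0], [1.0, 0.0]]),
        section_scores=scores,
    )
    fn.mass_correction = compute_mass_correction(anchors, num_sections=n)
    return fn


def compute_mass_correction(anchors: list[AnchorMatch], num_sections: int = 100) -> np.ndarray:
    """Piecewise-linear ppm-shift curve: per-NET-bin medians of delta-ppm.

    Bins without anchors inherit the nearest populated bin's value; the
    curve is pinned flat at NET 0 and 1 so evaluation never extrapolates.
    """
    if not anchors:
        raise AlignmentError("cannot compute a mass correction from zero anchors")
    nets = np.array([a.alignee_net for a in anchors])
    deltas = np.array([a.delta_ppm for a in anchors])
    idx = np.clip((nets * num_sections).astype(int), 0, num_sections - 1)
    centers = (np.arange(num_sections) + 0.5) / num_sections
    medians = np.full(num_sections, np.nan)
    for b in range(num_sections):
        sel = idx == b
        if np.any(sel):
            medians[b] = np.median(deltas[sel])
    populated = np.flatnonzero(~np.isnan(medians))
    # empty bins inherit the nearest populated bin
    nearest = populated[np.argmin(np.abs(np.arange(num_sections)[:, None] - populated[None, :]), axis=1)]
    medians = medians[nearest]
    curve = np.column_stack([centers, medians])
    curve = np.vstack([[0.0, medians[0]], curve, [1.0, medians[-1]]])
    return curve


def apply_alignment(features: list[LCMSFeature], fn: AlignmentFunction) -> list[LCMSFeature]:
    """Return calibrated copies: NET warped, mass shifted by -ppm(net).

    Originals are kept in ``raw_net`` / ``raw_monoisotopic_mass``.
    """
    out = []
    for f in features:
        raw_net = f.raw_net if not math.isnan(f.raw_net) else f.net
        new_net = float(fn.warp(raw_net))
        shift = float(fn.ppm_shift(raw_net))
        new_mass = f.raw_monoisotopic_mass * (1.0 - shift * 1e-6)
        out.append(
            replace(
                f,
                net=new_net,
                raw_net=raw_net,
                monoisotopic_mass=new_mass,
                raw_monoisotopic_mass=f.raw_monoisotopic_mass,
                member_ids=list(f.member_ids),
                spectrum_ids=list(f.spectrum_ids),
            )
        )
    return out


class LCMSWarpAligner(BaseEstimator):
    """Estimator facade: fit a warp to a baseline, transform features.

    Parameters mirror :class:`AlignmentParameters`.  After ``fit``:

    ``alignment_``
        the fitted :class:`AlignmentFunction`;
    ``section_scores_``
        the alignee-section x baseline-section anchor-score matrix;
    ``n_anchors_``
        number of anchor pairs used.
    """

    def __init__(
        self,
        num_sections: int = 100,
        max_expansion_factor: int = 3,
        match_mass_tolerance_ppm: float = 10.0,
    ):
        self.num_sections = num_sections
        self.max_expansion_factor = max_expansion_factor
        self.match_mass_tolerance_ppm = match_mass_tolerance_ppm

    def _params(self) -> AlignmentParameters:
        return AlignmentParameters(
            num_sections=self.num_sections,
            max_expansion_factor=self.max_expansion_factor,
            match_mass_tolerance_ppm=self.match_mass_tolerance_ppm,
        )

    def fit(self, X: list[LCMSFeature], baseline):
        """X: alignee features (NETs populated); baseline: features or tags."""
        anchors = find_anchor_matches(X, baseline, self.match_mass_tolerance_ppm)
        dataset_id = X[0].dataset_id if X else ""
        baseline_list = list(baseline)
        baseline_id = (
            "AMTDB"
            if baseline_list and isinstance(baseline_list[0], AMTTag)
            else (baseline_list[0].dataset_id if baseline_list else "")
        )
        self.alignment_ = compute_warp(
            anchors, self._params(), dataset_id=dataset_id, baseline_id=baseline_id
        )
        self.section_scores_ = self.alignment_.section_scores
        self.n_anchors_ = len(anchors)
        return self

    def transform(self, X: list[LCMSFeature]) -> list[LCMSFeature]:
        return apply_alignment(X, self.alignment_)

    def fit_transform(self, X, baseline):
        return self.fit(X, baseline).transform(X)
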