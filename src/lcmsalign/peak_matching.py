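"""Match feature clusters to AMT tags and score match confidence.

Candidate matches come from a simple range query: every (cluster, tag)
pair whose centroid mass and NET agree within the matching tolerances.
A cluster can match several tags, so each match gets two probabilities:

* a **match confidence** (STAC-style score): the posterior probability
  that the match belongs to the *true* component of a two-component
  mixture over the (delta_ppm, delta_net) errors — true matches follow a
  product of two normals concentrated near zero, false matches are
  uniform over the tolerance box.  The mixture is fitted to the observed
  candidates by expectation-maximization.
* a **uniqueness probability**: the confidence renormalized over all of
  the cluster's competing matches, i.e. the probability that *this*
  match is the correct one among them.  A uniqueness above 0.5 singles
  out at most one tag per cluster.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from sklearn.base import BaseEstimator

from .models import AMTTag, FeatureCluster, MatchMixtureModel, TagMatch
from .parameters import MatchingParameters

logger = logging.getLogger(__name__)

#: below this many candidates the EM fit is unreliable; a fixed prior
#: model is used instead
MIN_CANDIDATES_FOR_EM = 20


def range_query(
    clusters: list[FeatureCluster],
    tags: list[AMTTag],
    mass_tol_ppm: float = 10.0,
    net_tol: float = 0.03,
) -> list[TagMatch]:
    """All (cluster, tag) pairs within both matching tolerances."""
    tag_masses = np.array([t.monoisotopic_mass for t in tags])
    order = np.argsort(tag_masses, kind="stable")
    tag_masses = tag_masses[order]
    matches: list[TagMatch] = []
    for c in clusters:
        half_width = c.centroid_mass * mass_tol_ppm * 1e-6
        lo = np.searchsorted(tag_masses, c.centroid_mass - half_width * 1.001, "left")
        hi = np.searchsorted(tag_masses, c.centroid_mass + half_width * 1.001, "right")
        for k in range(int(lo), int(hi)):
            t = tags[int(order[k])]
            delta_ppm = 1e6 * (c.centroid_mass - t.monoisotopic_mass) / t.monoisotopic_mass
            delta_net = c.centroid_net - t.net
            if abs(delta_ppm) <= mass_tol_ppm and abs(delta_net) <= net_tol:
                matches.append(
                    TagMatch(
                        cluster_id=c.cluster_id,
                        tag_id=t.tag_id,
                        delta_ppm=float(delta_ppm),
                        delta_net=float(delta_net),
                    )
                )
    return matches


def _normal_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def fit_match_model(
    candidates: list[TagMatch],
    mass_tol_ppm: float = 10.0,
    net_tol: float = 0.03,
    max_iter: int = 500,
    tol: float = 1e-8,
    loglik_trace: list | None = None,
) -> MatchMixtureModel:
    """EM fit of the true-vs-false match mixture to candidate errors.

    Converges when the relative log-likelihood change drops below ``tol``
    (or after ``max_iter`` iterations).  With fewer than
    ``MIN_CANDIDATES_FOR_EM`` candidates a fixed prior model (pi=0.5,
    zero means, sd = tol/2) is returned with a warning.
    """
    if len(candidates) < MIN_CANDIDATES_FOR_EM:
        logger.warning(
            "only %d match candidates; using the fixed prior mixture model",
            len(candidates),
        )
        return MatchMixtureModel(
            pi_true=0.5,
            mean_ppm=0.0,
            sd_ppm=mass_tol_ppm / 2.0,
            mean_net=0.0,
            sd_net=net_tol / 2.0,
            mass_tol_ppm=mass_tol_ppm,
            net_tol=net_tol,
            n_candidates=len(candidates),
            converged=False,
        )

    x = np.array([m.delta_ppm for m in candidates])
    y = np.array([m.delta_net for m in candidates])
    n = len(x)
    u = 1.0 / (4.0 * mass_tol_ppm * net_tol)  # uniform density over the box

    # floor the sds at 5% of the tolerance window: sharper peaks are not
    # resolvable by the match errors, and an unbounded normal component
    # would otherwise collapse onto the tightest candidates (the classic
    # degenerate-likelihood EM solution) when nearly all matches are true
    sd_ppm_floor = mass_tol_ppm / 20.0
    sd_net_floor = net_tol / 20.0

    pi = 0.5
    mu_x, mu_y = 0.0, 0.0
    sd_x, sd_y = mass_tol_ppm / 2.0, net_tol / 2.0
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        f_true = _normal_pdf(x, mu_x, sd_x) * _normal_pdf(y, mu_y, sd_y)
        num = pi * f_true
        den = num + (1.0 - pi) * u
        resp = num / den
        ll = float(np.sum(np.log(den)))
        if loglik_trace is not None:
            loglik_trace.append(ll)
        if prev_ll != -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        w = resp.sum()
        pi = float(w / n)
        pi = min(max(pi, 1e-9), 1.0 - 1e-9)
        if w > 0:
            mu_x = float((resp * x).sum() / w)
            mu_y = float((resp * y).sum() / w)
            sd_x = max(math.sqrt(float((resp * (x - mu_x) ** 2).sum() / w)), sd_ppm_floor)
            sd_y = max(math.sqrt(float((resp * (y - mu_y) ** 2).sum() / w)), sd_net_floor)
    return MatchMixtureModel(
        pi_true=pi,
        mean_ppm=mu_x,
        sd_ppm=sd_x,
        mean_net=mu_y,
        sd_net=sd_y,
        mass_tol_ppm=mass_tol_ppm,
        net_tol=net_tol,
        n_candidates=n,
        converged=converged,
    )


def stac_score(match: TagMatch, model: MatchMixtureModel) -> float:
    """Posterior probability that the match is a true match."""
    f_true = float(
        _normal_pdf(np.array(match.delta_ppm), model.mean_ppm, model.sd_ppm)
        * _normal_pdf(np.array(match.delta_net), model.mean_net, model.sd_net)
    )
    num = model.pi_true * f_true
    den = num + (1.0 - model.pi_true) * model.false_density
    if den == 0.0:
        return 0.0
    return num / den


def uniqueness_probability(matches: list[TagMatch]) -> None:
    """Assign per-match uniqueness: the match's score renormalized over
    all matches of the same cluster (in place; scores must be set).

    Per cluster the uniqueness values sum to 1; a cluster with a single
    match gets 1.0.  If every score of a cluster is zero the mass/NET
    errors carry no signal and uniqueness falls back to uniform (warned).
    """
    by_cluster: dict[int, list[TagMatch]] = {}
    for m in matches:
        by_cluster.setdefault(m.cluster_id, []).append(m)
    for cluster_id, group in by_cluster.items():
        total = sum(m.stac for m in group)
        if total <= 0.0:
            logger.warning(
                "cluster %d: all match scores zero; uniform uniqueness", cluster_id
            )
            for m in group:
                m.uniqueness = 1.0 / len(group)
        else:
            for m in group:
                m.uniqueness = m.stac / total


class StacScorer(BaseEstimator):
    """Estimator facade: fit the mixture on candidates, score matches.

    After ``fit``: ``model_`` (:class:`MatchMixtureModel`) plus the
    mirrored scalar attributes ``pi_true_``, ``sd_ppm_``, ``sd_net_``.
    ``predict_proba`` returns the true-match posterior for (n, 2) arrays
    of (delta_ppm, delta_net).
    """

    def __init__(self, mass_tolerance_ppm: float = 10.0, net_tolerance: float = 0.03):
        self.mass_tolerance_ppm = mass_tolerance_ppm
        self.net_tolerance = net_tolerance

    def fit(self, X, y=None):
        """X: list of TagMatch, or array-like (n, 2) of delta errors."""
        candidates = self._as_candidates(X)
        self.model_ = fit_match_model(
            candidates, self.mass_tolerance_ppm, self.net_tolerance
        )
        self.pi_true_ = self.model_.pi_true
        self.sd_ppm_ = self.model_.sd_ppm
        self.sd_net_ = self.model_.sd_net
        return self

    @staticmethod
    def _as_candidates(X) -> list[TagMatch]:
        if len(X) and isinstance(X[0], TagMatch):
            return list(X)
        arr = np.asarray(X, dtype=float).reshape(-1, 2)
        return [
            TagMatch(cluster_id=i, tag_id="", delta_ppm=float(a), delta_net=float(b))
            for i, (a, b) in enumerate(arr)
        ]

    def predict_proba(self, X) -> np.ndarray:
        candidates = self._as_candidates(X)
        return np.array([stac_score(m, self.model_) for m in candidates])

    def score_matches(self, matches: list[TagMatch]) -> list[TagMatch]:
        """Set ``stac`` and ``uniqueness`` on the given matches in place."""
        for m in matches:
            m.stac = stac_score(m, self.model_)
        uniqueness_probability(matches)
        return matches


def match_clusters_to_tags(
    clusters: list[FeatureCluster],
    tags: list[AMTTag],
    params: MatchingParameters | None = None,
) -> tuple[list[TagMatch], MatchMixtureModel]:
    """Range query + mixture fit + confidence and uniqueness scoring."""
    params = params or MatchingParameters()
    matches = range_query(clusters, tags, params.mass_tolerance_ppm, params.net_tolerance)
    scorer = StacScorer(params.mass_tolerance_ppm, params.net_tolerance).fit(matches)
    if params.stac_enabled:
        scorer.score_matches(matches)
    else:
        for m in matches:
            m.stac = 1.0
        uniqueness_probability(matches)
    return matches, scorer.model_
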