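"""Core domain objects for multi-dataset LC-MS analysis.

The analysis vocabulary:

* an **MS feature** is one deisotoped detection in one mass spectrum —
  a monoisotopic mass with a charge, scan number, abundance and an
  isotopic-fit score (lower fit = better match to the theoretical
  isotope envelope);
* an **LC-MS feature** groups MS features of a common monoisotopic mass
  across consecutive elution scans;
* a **feature cluster** groups LC-MS features across aligned datasets;
* an **AMT tag** is a reference entry (peptide sequence, accurate
  monoisotopic mass, globally averaged normalized elution time) used to
  identify LC-MS features without fresh MS/MS;
* **NET** (normalized elution time) rescales elution position to [0, 1]
  so runs of differing length or gradient are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Mass of a proton in Dalton; used to convert between m/z and neutral
#: monoisotopic mass: m/z = (M + z * PROTON_MASS) / z.
PROTON_MASS = 1.00727646688


def ppm_between(mass_a: float, mass_b: float) -> float:
    """Relative mass difference in parts per million, |dm| / mean(m) * 1e6."""
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("masses must be positive")
    return 1e6 * abs(mass_a - mass_b) / ((mass_a + mass_b) / 2.0)


@dataclass
class MSFeature:
    """One deisotoped isotopic-distribution detection."""

    dataset_id: str
    feature_id: int
    scan: int
    charge: int
    mz: float
    monoisotopic_mass: float
    abundance: float
    isotopic_fit: float

    def __post_init__(self) -> None:
        if self.scan < 1:
            raise ValueError(f"scan must be >= 1, got {self.scan}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic_mass must be positive")
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.abundance < 0:
            raise ValueError("abundance must be nonnegative")
        # m/z and neutral mass must agree through the charge relation.
        implied = self.mz * self.charge - self.charge * PROTON_MASS
        if abs(implied - self.monoisotopic_mass) / self.monoisotopic_mass > 100e-6:
            raise ValueError(
                f"mz {self.mz} and monoisotopic_mass {self.monoisotopic_mass} "
                f"inconsistent at charge {self.charge} (> 100 ppm)"
            )


@dataclass
class MSnSpectrum:
    """A fragmentation (MS level >= 2) spectrum with its precursor."""

    dataset_id: str
    spectrum_id: int
    scan: int
    ms_level: int
    precursor_mz: float
    precursor_charge: int  # 0 = unknown
    peaks: np.ndarray  # shape (n, 2): mz, intensity; sorted by mz

    def __post_init__(self) -> None:
        if self.ms_level < 2:
            raise ValueError("ms_level must be >= 2")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]


@dataclass
class AMTTag:
    """Accurate-mass-and-time reference entry."""

    tag_id: str
    sequence: str
    monoisotopic_mass: float
    net: float
    observation_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.net <= 1.0:
            raise ValueError(f"net must lie in [0, 1], got {self.net}")
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic_mass must be positive")


@dataclass
class LCMSFeature:
    """A group of MS features contiguous in elution at a common mass.

    ``monoisotopic_mass`` and ``net`` are the *calibrated* coordinates used
    for cross-dataset comparison; the pre-alignment values are retained in
    ``raw_monoisotopic_mass`` / ``raw_net``.
    """

    dataset_id: str
    lcms_id: int
    member_ids: list[int]
    monoisotopic_mass: float
    scan_start: int
    scan_end: int
    representative_scan: int
    abundance: float
    charges: frozenset[int]
    net: float = math.nan
    raw_net: float = math.nan
    raw_monoisotopic_mass: float = math.nan
    spectrum_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("an LC-MS feature needs at least one member")
        if not self.scan_start <= self.representative_scan <= self.scan_end:
            raise ValueError("representative scan outside the scan span")
        if math.isnan(self.raw_monoisotopic_mass):
            self.raw_monoisotopic_mass = self.monoisotopic_mass


@dataclass
class FeatureCluster:
    """A set of LC-MS features from multiple aligned datasets.

    ``tightness`` is the mean normalized L2 distance of members to the
    centroid (smaller = tighter); ``ambiguity`` is the minimum member-pair
    distance to any neighboring cluster (smaller = more ambiguous,
    ``inf`` when the cluster has no neighbor).
    """

    cluster_id: int
    members: list[LCMSFeature]
    centroid_mass: float
    centroid_net: float
    tightness: float = math.nan
    ambiguity: float = math.inf

    @property
    def dataset_count(self) -> int:
        return len({m.dataset_id for m in self.members})

    @property
    def member_count(self) -> int:
        return len(self.members)


@dataclass
class AnchorMatch:
    """A candidate (alignee feature, baseline entry) pair feeding the warp."""

    alignee_net: float
    baseline_net: float
    delta_ppm: float
    alignee_mass: float


@dataclass
class AlignmentFunction:
    """Piecewise-linear NET warp plus a piecewise mass recalibration.

    ``knots`` maps alignee NET to baseline NET (strictly increasing in both
    coordinates); ``mass_correction`` gives the systematic ppm shift as a
    function of alignee NET; ``section_scores`` is the alignee-section x
    baseline-section anchor-score matrix behind the alignment heat maps.
    """

    dataset_id: str
    baseline_id: str
    knots: np.ndarray  # shape (k, 2): (alignee_net, baseline_net)
    mass_correction: np.ndarray  # shape (m, 2): (alignee_net, ppm_shift)
    section_scores: np.ndarray  # shape (num_sections, num_sections)

    def warp(self, x) -> np.ndarray:
        """Evaluate the NET warp, clamped to [0, 1]."""
        y = np.interp(np.asarray(x, dtype=float), self.knots[:, 0], self.knots[:, 1])
        return np.clip(y, 0.0, 1.0)

    def ppm_shift(self, x) -> np.ndarray:
        """Evaluate the mass-correction curve (ppm) at alignee NET x."""
        return np.interp(
            np.asarray(x, dtype=float),
            self.mass_correction[:, 0],
            self.mass_correction[:, 1],
        )

    @classmethod
    def identity(cls, dataset_id: str, baseline_id: str, num_sections: int = 100):
        return cls(
            dataset_id=dataset_id,
            baseline_id=baseline_id,
            knots=np.array([[0.0, 0.0], [1.0, 1.0]]),
            mass_correction=np.array([[0.0, 0.0], [1.0, 0.0]]),
            section_scores=np.zeros((num_sections, num_sections)),
        )


@dataclass
class TagMatch:
    """One (cluster, AMT tag) match with its confidence scores."""

    cluster_id: int
    tag_id: str
    delta_ppm: float
    delta_net: float
    stac: float = math.nan
    uniqueness: float = math.nan


@dataclass
class MatchMixtureModel:
    """Two-component model over (delta_ppm, delta_net) match errors.

    True matches follow a product of two normals; false matches are uniform
    over the tolerance box.  The posterior of the true component is the
    match confidence (STAC-style score).
    """

    pi_true: float
    mean_ppm: float
    sd_ppm: float
    mean_net: float
    sd_net: float
    mass_tol_ppm: float
    net_tol: float
    n_candidates: int = 0
    converged: bool = True

    @property
    def false_density(self) -> float:
        return 1.0 / (4.0 * self.mass_tol_ppm * self.net_tol)


@dataclass
class ProcessedSpectrum:
    """A spectrum reduced to a unit-norm binned peak vector."""

    dataset_id: str
    spectrum_id: int
    scan: int
    precursor_mz: float
    bins: dict[int, float]  # bin index -> normalized intensity weight
    total_intensity: float


@dataclass
class SpectralCluster:
    """A cluster of MS/MS spectra across datasets."""

    cluster_id: int
    members: list[ProcessedSpectrum]
    representative: ProcessedSpectrum


@dataclass
class TracebackRecord:
    """One resolved cluster -> LC-MS feature -> MS/MS spectrum link."""

    cluster_id: int
    dataset_id: str
    lcms_id: int
    spectrum_id: int
    scan: int
    precursor_mz: float
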