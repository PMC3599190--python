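"""Analysis parameters and their file representations (YAML or XML).

Every tolerance that gates an algorithm lives here so a whole analysis is
reproducible from one parameter file.  Unknown keys in a parameter file
warn but never fail, so files written by newer versions stay loadable.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class FeatureFindingParameters:
    #: maximum mass difference (ppm) for two MS features to join one LC-MS feature
    mass_tolerance_ppm: float = 10.0
    #: maximum scan gap between joined MS features
    scan_gap_tolerance: int = 5
    #: minimum number of MS features per LC-MS feature
    min_feature_length: int = 1
    #: weights of the mass / elution-time / log-intensity axes in the
    #: weighted L2 distance (intensity off by default so saturated elution
    #: profiles are not split on intensity dips)
    w_mass: float = 1.0
    w_time: float = 1.0
    w_intensity: float = 0.0


@dataclass
class LoadingFilters:
    #: keep rows with isotopic fit <= this (lower fit = better); None = keep all
    max_isotopic_fit: float | None = 0.15
    #: keep rows with abundance >= this
    min_abundance: float = 0.0


@dataclass
class AlignmentParameters:
    #: number of NET sections on each axis of the warp score matrix
    num_sections: int = 100
    #: maximum section step (expansion/contraction factor) of the warp
    max_expansion_factor: int = 3
    #: mass tolerance (ppm) for anchor-pair candidates
    match_mass_tolerance_ppm: float = 10.0


@dataclass
class ClusteringParameters:
    #: "single" or "average" linkage
    method: str = "single"
    mass_tolerance_ppm: float = 10.0
    net_tolerance: float = 0.03


@dataclass
class MatchingParameters:
    mass_tolerance_ppm: float = 10.0
    net_tolerance: float = 0.03
    stac_enabled: bool = True


@dataclass
class TracebackParameters:
    #: tolerance (Thomson) between MS/MS precursor m/z and the feature's
    #: per-charge reconstructed m/z
    precursor_mz_tolerance: float = 0.05
    #: scans beyond a feature's span within which a spectrum may still link
    scan_window: int = 10


@dataclass
class SpectralParameters:
    #: m/z bin width (Th) for spectral vectorization; 1.0005 tracks the
    #: peptide mass-defect spacing
    bin_width: float = 1.0005
    top_k_peaks: int = 50
    similarity_threshold: float = 0.7


@dataclass
class AnalysisParameters:
    feature_finding: FeatureFindingParameters = field(default_factory=FeatureFindingParameters)
    loading_filters: LoadingFilters = field(default_factory=LoadingFilters)
    alignment: AlignmentParameters = field(default_factory=AlignmentParameters)
    clustering: ClusteringParameters = field(default_factory=ClusteringParameters)
    matching: MatchingParameters = field(default_factory=MatchingParameters)
    traceback: TracebackParameters = field(default_factory=TracebackParameters)
    spectral: SpectralParameters = field(default_factory=SpectralParameters)
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self
        positives = {
            "feature_finding.mass_tolerance_ppm": p.feature_finding.mass_tolerance_ppm,
            "alignment.match_mass_tolerance_ppm": p.alignment.match_mass_tolerance_ppm,
            "clustering.mass_tolerance_ppm": p.clustering.mass_tolerance_ppm,
            "clustering.net_tolerance": p.clustering.net_tolerance,
            "matching.mass_tolerance_ppm": p.matching.mass_tolerance_ppm,
            "matching.net_tolerance": p.matching.net_tolerance,
            "traceback.precursor_mz_tolerance": p.traceback.precursor_mz_tolerance,
            "spectral.bin_width": p.spectral.bin_width,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if p.clustering.method not in ("single", "average"):
            raise ValueError(
                f"clustering.method must be 'single' or 'average', got {p.clustering.method!r}"
            )
        if p.alignment.num_sections < 2:
            raise ValueError("alignment.num_sections must be >= 2")
        if p.alignment.max_expansion_factor < 1:
            raise ValueError("alignment.max_expansion_factor must be >= 1")
        if min(p.feature_finding.w_mass, p.feature_finding.w_time, p.feature_finding.w_intensity) < 0:
            raise ValueError("feature distance weights must be nonnegative")
        if max(p.feature_finding.w_mass, p.feature_finding.w_time, p.feature_finding.w_intensity) <= 0:
            raise ValueError("at least one feature distance weight must be positive")

    # -- dict / file round-trips ------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisParameters":
        kwargs: dict = {}
        sections = {f.name: f for f in fields(cls)}
        for key, value in data.items():
            if key not in sections:
                warnings.warn(f"unknown parameter section {key!r} ignored")
                continue
            f = sections[key]
            if key == "seed":
                kwargs[key] = int(value)
                continue
            sub_cls = f.default_factory  # the section dataclass
            sub_fields = {sf.name: sf for sf in fields(sub_cls)}
            sub_kwargs = {}
            for sub_key, sub_value in (value or {}).items():
                if sub_key not in sub_fields:
                    warnings.warn(f"unknown parameter {key}.{sub_key!r} ignored")
                    continue
                sub_kwargs[sub_key] = _coerce(sub_value, sub_fields[sub_key].type)
            kwargs[key] = sub_cls(**sub_kwargs)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_xml(self, path) -> None:
        root = ET.Element("parameters")
        for key, value in self.to_dict().items():
            if key == "seed":
                ET.SubElement(root, "seed").text = str(value)
                continue
            section = ET.SubElement(root, key)
            for sub_key, sub_value in value.items():
                ET.SubElement(section, sub_key).text = "" if sub_value is None else str(sub_value)
        ET.indent(root)
        ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)

    @classmethod
    def from_file(cls, path) -> "AnalysisParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".xml" or text.lstrip().startswith("<"):
            return cls.from_dict(_xml_to_dict(text))
        return cls.from_dict(yaml.safe_load(text) or {})


def _coerce(value, annotation):
    """Coerce a parsed scalar (possibly a string from XML) to its field type."""
    if value is None or value == "":
        return None
    ann = str(annotation)
    if "bool" in ann:
        if isinstance(value, str):
            return value.strip().lower() in ("1", "true", "yes", "on")
        return bool(value)
    if "int" in ann and "float" not in ann:
        return int(float(value))
    if "float" in ann:
        return float(value)
    return value


def _xml_to_dict(text: str) -> dict:
    root = ET.fromstring(text)
    data: dict = {}
    for section in root:
        if section.tag == "seed":
            data["seed"] = int(section.text)
            continue
        data[section.tag] = {child.tag: child.text for child in section}
    return data
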