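"""SQLite persistence of a complete analysis.

The schema keeps one join path from clusters down to spectra so the full
traceback (cluster -> member LC-MS features -> linked MS/MS spectra) can
run in SQL:

    clusters -> cluster_members -> lcms_features
             -> spectrum_links  -> spectra

plus ``feature_members`` (LC-MS feature -> raw MS feature rows),
``matches`` (cluster -> AMT tag), ``alignments`` (per-dataset warp) and a
``parameters`` key/value table capturing the full analysis configuration.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    AMTTag,
    AlignmentFunction,
    FeatureCluster,
    LCMSFeature,
    MSFeature,
    MSnSpectrum,
    TagMatch,
)
from .parameters import AnalysisParameters

_SCHEMA = """
CREATE TABLE datasets (
    dataset_id TEXT PRIMARY KEY,
    isos_path TEXT,
    spectra_path TEXT,
    role TEXT
);
CREATE TABLE ms_features (
    dataset_id TEXT NOT NULL REFERENCES datasets(dataset_id),
    feature_id INTEGER NOT NULL,
    scan INTEGER NOT NULL,
    charge INTEGER NOT NULL,
    mz REAL NOT NULL,
    monoisotopic_mass REAL NOT NULL,
    abundance REAL NOT NULL,
    isotopic_fit REAL NOT NULL,
    PRIMARY KEY (dataset_id, feature_id)
);
CREATE TABLE lcms_features (
    dataset_id TEXT NOT NULL REFERENCES datasets(dataset_id),
    lcms_id INTEGER NOT NULL,
    monoisotopic_mass REAL NOT NULL,
    raw_monoisotopic_mass REAL NOT NULL,
    scan_start INTEGER NOT NULL,
    scan_end INTEGER NOT NULL,
    representative_scan INTEGER NOT NULL,
    net REAL,
    raw_net REAL,
    abundance REAL NOT NULL,
    charges TEXT NOT NULL,
    PRIMARY KEY (dataset_id, lcms_id)
);
CREATE TABLE feature_members (
    dataset_id TEXT NOT NULL,
    lcms_id INTEGER NOT NULL,
    feature_id INTEGER NOT NULL,
    FOREIGN KEY (dataset_id, lcms_id) REFERENCES lcms_features(dataset_id, lcms_id),
    FOREIGN KEY (dataset_id, feature_id) REFERENCES ms_features(dataset_id, feature_id)
);
CREATE TABLE clusters (
    cluster_id INTEGER PRIMARY KEY,
    centroid_mass REAL NOT NULL,
    centroid_net REAL NOT NULL,
    tightness REAL,
    ambiguity REAL,
    dataset_count INTEGER NOT NULL,
    member_count INTEGER NOT NULL
);
CREATE TABLE cluster_members (
    cluster_id INTEGER NOT NULL REFERENCES clusters(cluster_id),
    dataset_id TEXT NOT NULL,
    lcms_id INTEGER NOT NULL,
    FOREIGN KEY (dataset_id, lcms_id) REFERENCES lcms_features(dataset_id, lcms_id)
);
CREATE TABLE amt_tags (
    tag_id TEXT PRIMARY KEY,
    sequence TEXT NOT NULL,
    monoisotopic_mass REAL NOT NULL,
    net REAL NOT NULL,
    observation_count INTEGER NOT NULL
);
CREATE TABLE matches (
    cluster_id INTEGER NOT NULL REFERENCES clusters(cluster_id),
    tag_id TEXT NOT NULL REFERENCES amt_tags(tag_id),
    delta_ppm REAL NOT NULL,
    delta_net REAL NOT NULL,
    stac REAL,
    uniqueness REAL
);
CREATE TABLE spectra (
    dataset_id TEXT NOT NULL REFERENCES datasets(dataset_id),
    spectrum_id INTEGER NOT NULL,
    scan INTEGER NOT NULL,
    ms_level INTEGER NOT NULL,
    precursor_mz REAL NOT NULL,
    precursor_charge INTEGER NOT NULL,
    peaks TEXT NOT NULL,
    PRIMARY KEY (dataset_id, spectrum_id)
);
CREATE TABLE spectrum_links (
    dataset_id TEXT NOT NULL,
    lcms_id INTEGER NOT NULL,
    spectrum_id INTEGER NOT NULL,
    FOREIGN KEY (dataset_id, lcms_id) REFERENCES lcms_features(dataset_id, lcms_id),
    FOREIGN KEY (dataset_id, spectrum_id) REFERENCES spectra(dataset_id, spectrum_id)
);
CREATE TABLE alignments (
    dataset_id TEXT PRIMARY KEY,
    baseline_id TEXT NOT NULL,
    knots TEXT NOT NULL,
    mass_correction TEXT NOT NULL
);
CREATE TABLE parameters (
    key TEXT PRIMARY KEY,
    value TEXT
);
CREATE INDEX idx_cluster_members ON cluster_members(cluster_id);
CREATE INDEX idx_spectrum_links ON spectrum_links(dataset_id, lcms_id);
"""


@dataclass
class AnalysisState:
    """Everything an analysis run produces, in memory."""

    parameters: AnalysisParameters = field(default_factory=AnalysisParameters)
    dataset_info: dict[str, dict] = field(default_factory=dict)  # id -> paths/role
    ms_features: dict[str, list[MSFeature]] = field(default_factory=dict)
    lcms_features: dict[str, list[LCMSFeature]] = field(default_factory=dict)
    spectra: dict[str, list[MSnSpectrum]] = field(default_factory=dict)
    alignments: dict[str, AlignmentFunction] = field(default_factory=dict)
    clusters: list[FeatureCluster] = field(default_factory=list)
    tags: list[AMTTag] = field(default_factory=list)
    matches: list[TagMatch] = field(default_factory=list)
    spectral_clusters: list = field(default_factory=list)  # not persisted

    @property
    def dataset_order(self) -> list[str]:
        return list(self.dataset_info) or sorted(self.lcms_features)


def _flatten_parameters(params: AnalysisParameters) -> list[tuple[str, str]]:
    rows = []
    for section, value in params.to_dict().items():
        if section == "seed":
            rows.append(("seed", str(value)))
            continue
        for key, sub_value in value.items():
            rows.append((f"{section}.{key}", "" if sub_value is None else str(sub_value)))
    return rows


def persist_results(state: AnalysisState, path, overwrite: bool = False) -> None:
    """Write the full analysis to a SQLite database file."""
    path = Path(path)
    if path.exists():
        if not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        for ds in state.dataset_order:
            info = state.dataset_info.get(ds, {})
            con.execute(
                "INSERT INTO datasets VALUES (?,?,?,?)",
                (ds, info.get("isos_path"), info.get("spectra_path"), info.get("role")),
            )
        for ds, feats in state.ms_features.items():
            con.executemany(
                "INSERT INTO ms_features VALUES (?,?,?,?,?,?,?,?)",
                [
                    (f.dataset_id, f.feature_id, f.scan, f.charge, f.mz,
                     f.monoisotopic_mass, f.abundance, f.isotopic_fit)
                    for f in feats
                ],
            )
        for ds, feats in state.lcms_features.items():
            con.executemany(
                "INSERT INTO lcms_features VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                [
                    (f.dataset_id, f.lcms_id, f.monoisotopic_mass,
                     f.raw_monoisotopic_mass, f.scan_start, f.scan_end,
                     f.representative_scan, f.net, f.raw_net, f.abundance,
                     ",".join(str(z) for z in sorted(f.charges)))
                    for f in feats
                ],
            )
            con.executemany(
                "INSERT INTO feature_members VALUES (?,?,?)",
                [
                    (f.dataset_id, f.lcms_id, mid)
                    for f in feats
                    for mid in f.member_ids
                ],
            )
            con.executemany(
                "INSERT INTO spectrum_links VALUES (?,?,?)",
                [
                    (f.dataset_id, f.lcms_id, sid)
                    for f in feats
                    for sid in sorted(f.spectrum_ids)
                ],
            )
        for c in state.clusters:
            con.execute(
                "INSERT INTO clusters VALUES (?,?,?,?,?,?,?)",
                (c.cluster_id, c.centroid_mass, c.centroid_net, c.tightness,
                 c.ambiguity, c.dataset_count, c.member_count),
            )
            con.executemany(
                "INSERT INTO cluster_members VALUES (?,?,?)",
                [(c.cluster_id, m.dataset_id, m.lcms_id) for m in c.members],
            )
        con.executemany(
            "INSERT INTO amt_tags VALUES (?,?,?,?,?)",
            [
                (t.tag_id, t.sequence, t.monoisotopic_mass, t.net, t.observation_count)
                for t in state.tags
            ],
        )
        con.executemany(
            "INSERT INTO matches VALUES (?,?,?,?,?,?)",
            [
                (m.cluster_id, m.tag_id, m.delta_ppm, m.delta_net, m.stac, m.uniqueness)
                for m in state.matches
            ],
        )
        for ds, spectra in state.spectra.items():
            con.executemany(
                "INSERT INTO spectra VALUES (?,?,?,?,?,?,?)",
                [
                    (s.dataset_id, s.spectrum_id, s.scan, s.ms_level, s.precursor_mz,
                     s.precursor_charge, json.dumps(s.peaks.tolist()))
                    for s in spectra
                ],
            )
        con.executemany(
            "INSERT INTO alignments VALUES (?,?,?,?)",
            [
                (ds, fn.baseline_id, json.dumps(fn.knots.tolist()),
                 json.dumps(fn.mass_correction.tolist()))
                for ds, fn in state.alignments.items()
            ],
        )
        con.executemany("INSERT INTO parameters VALUES (?,?)",
                        _flatten_parameters(state.parameters))
        con.commit()
    finally:
        con.close()


class ResultsStore:
    """Read-side wrapper over a persisted results database."""

    def __init__(self, path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(f"no results database at {self.path}")
        self.con = sqlite3.connect(self.path)
        self.con.row_factory = sqlite3.Row

    def close(self) -> None:
        self.con.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- simple accessors --------------------------------------------------

    def table_count(self, table: str) -> int:
        if not table.isidentifier():
            raise ValueError(f"bad table name {table!r}")
        return self.con.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def dataset_ids(self) -> list[str]:
        return [r[0] for r in self.con.execute("SELECT dataset_id FROM datasets")]

    def parameters(self) -> dict[str, str]:
        return dict(self.con.execute("SELECT key, value FROM parameters"))

    def cluster_ids(self) -> list[int]:
        return [r[0] for r in self.con.execute("SELECT cluster_id FROM clusters ORDER BY cluster_id")]

    def cluster_row(self, cluster_id: int) -> sqlite3.Row:
        row = self.con.execute(
            "SELECT * FROM clusters WHERE cluster_id = ?", (cluster_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown cluster id {cluster_id}")
        return row

    def spectra_for_cluster(self, cluster_id: int) -> list[sqlite3.Row]:
        """The single SQL join path from a cluster to its MS/MS spectra."""
        self.cluster_row(cluster_id)  # raises on unknown id
        return self.con.execute(
            """
            SELECT cm.cluster_id, cm.dataset_id, cm.lcms_id,
                   sp.spectrum_id, sp.scan, sp.precursor_mz, sp.peaks
            FROM cluster_members cm
            JOIN spectrum_links sl
              ON sl.dataset_id = cm.dataset_id AND sl.lcms_id = cm.lcms_id
            JOIN spectra sp
              ON sp.dataset_id = sl.dataset_id AND sp.spectrum_id = sl.spectrum_id
            WHERE cm.cluster_id = ?
            ORDER BY cm.dataset_id, cm.lcms_id, sp.spectrum_id
            """,
            (cluster_id,),
        ).fetchall()

    def spectrum_peaks(self, dataset_id: str, spectrum_id: int) -> np.ndarray:
        row = self.con.execute(
            "SELECT peaks FROM spectra WHERE dataset_id = ? AND spectrum_id = ?",
            (dataset_id, spectrum_id),
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown spectrum ({dataset_id}, {spectrum_id})")
        return np.array(json.loads(row[0]), dtype=float).reshape(-1, 2)
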