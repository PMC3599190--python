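"""Readers and writers for the external file formats.

Inputs: deisotoped MS feature tables in the DeconTools "isos" CSV dialect,
MS/MS spectra as MGF or a minimal mzXML subset (scan number, MS level,
precursor m/z, peak list), and AMT-tag reference tables as CSV or SQLite.
Outputs: the cross-tab cluster CSV and alignment score matrices.  The
SQLite results database lives in :mod:`lcmsalign.store`.
"""

from __future__ import annotations

import csv
import logging
import math
import re
import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics import mzxml as _mzxml

from .models import AMTTag, FeatureCluster, MSFeature, MSnSpectrum
from .parameters import LoadingFilters

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


# ---------------------------------------------------------------------------
# isos CSV (deisotoped MS features)
# ---------------------------------------------------------------------------

#: canonical column -> accepted aliases (all matched case-insensitively)
ISOS_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "scan": ("scan_num", "scan", "scannum", "frame_num"),
    "charge": ("charge", "charge_state", "z"),
    "abundance": ("abundance", "intensity", "abundance_sum"),
    "mz": ("mz", "m/z", "m/z_value"),
    "isotopic_fit": ("fit", "isotopic_fit", "fit_score"),
    "monoisotopic_mass": ("monoisotopic_mw", "monoisotopic_mass", "mono_mass", "monoisotopic mass"),
}

_NUMERIC_INT = ("scan", "charge")


def _resolve_isos_columns(header: list[str], aliases=None) -> dict[str, str]:
    alias_map = dict(ISOS_COLUMN_ALIASES)
    if aliases:
        for canonical, extra in aliases.items():
            alias_map[canonical] = tuple(alias_map.get(canonical, ())) + tuple(extra)
    lower = {h.strip().lower(): h for h in header}
    resolved = {}
    for canonical, names in alias_map.items():
        for name in names:
            if name.lower() in lower:
                resolved[canonical] = lower[name.lower()]
                break
        else:
            raise FormatError(
                f"isos CSV is missing required column {canonical!r} "
                f"(accepted names: {', '.join(names)})"
            )
    return resolved


def read_isos_csv(
    path,
    filters: LoadingFilters | None = None,
    dataset_id: str | None = None,
    column_aliases: dict | None = None,
) -> list[MSFeature]:
    """Read one dataset's deisotoped MS features, applying loading filters.

    Rows with isotopic fit above ``filters.max_isotopic_fit`` (fit scores:
    lower is better) or abundance below ``filters.min_abundance`` are
    dropped.  ``dataset_id`` defaults to the file stem.
    """
    path = Path(path)
    filters = filters or LoadingFilters(max_isotopic_fit=None, min_abundance=0.0)
    dataset_id = dataset_id if dataset_id is not None else path.stem

    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected an isos CSV header") from None
    resolved = _resolve_isos_columns(list(raw.columns), column_aliases)

    table = pd.DataFrame()
    for canonical, source in resolved.items():
        converted = pd.to_numeric(raw[source], errors="coerce")
        bad = converted.isna() & raw[source].notna() & (raw[source].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric value {raw[source][bad.idxmax()]!r} "
                f"in column {source!r} at line {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 2
            raise FormatError(f"{path}: missing value in column {source!r} at line {row}")
        # numpy's parser is correctly rounded (exact round trips);
        # pd.to_numeric above is only used to locate bad cells
        table[canonical] = raw[source].to_numpy(dtype=float)

    keep = pd.Series(True, index=table.index)
    if filters.max_isotopic_fit is not None:
        keep &= table["isotopic_fit"] <= filters.max_isotopic_fit
    keep &= table["abundance"] >= filters.min_abundance
    table = table[keep]

    features = []
    for feature_id, row in enumerate(table.itertuples(index=False)):
        features.append(
            MSFeature(
                dataset_id=dataset_id,
                feature_id=feature_id,
                scan=int(row.scan),
                charge=int(row.charge),
                mz=float(row.mz),
                monoisotopic_mass=float(row.monoisotopic_mass),
                abundance=float(row.abundance),
                isotopic_fit=float(row.isotopic_fit),
            )
        )
    return features


def write_isos_csv(features: list[MSFeature], path) -> None:
    """Write MS features back out in the isos dialect (round-trip aid)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scan_num", "charge", "abundance", "mz", "fit", "monoisotopic_mw"])
        for f in features:
            writer.writerow(
                [f.scan, f.charge, repr(f.abundance), repr(f.mz), repr(f.isotopic_fit),
                 repr(f.monoisotopic_mass)]
            )


# ---------------------------------------------------------------------------
# MS/MS spectra (MGF, minimal mzXML subset)
# ---------------------------------------------------------------------------

_SCAN_RE = re.compile(r"scan[=_\s:]*(\d+)", re.IGNORECASE)


def read_spectra(path, dataset_id: str | None = None) -> list[MSnSpectrum]:
    """Read MS/MS spectra from MGF or mzXML; sorted by scan, peaks by m/z.

    Spectra without a precursor m/z are skipped with a warning (they carry
    no information the traceback can use).  In mzXML input, MS1 scans are
    skipped silently.
    """
    path = Path(path)
    dataset_id = dataset_id if dataset_id is not None else path.stem
    if path.suffix.lower() == ".mzxml":
        spectra = _read_mzxml(path, dataset_id)
    else:
        spectra = _read_mgf(path, dataset_id)
    spectra.sort(key=lambda s: (s.scan, s.spectrum_id))
    return spectra


def _read_mgf(path: Path, dataset_id: str) -> list[MSnSpectrum]:
    if path.stat().st_size == 0:
        return []
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                logger.warning("%s: spectrum #%d has no PEPMASS; skipped", path, index)
                continue
            scan = _extract_scan(params, index)
            charge = 0
            if params.get("charge"):
                charge = int(params["charge"][0])
            peaks = np.column_stack(
                [np.asarray(entry["m/z array"], float), np.asarray(entry["intensity array"], float)]
            )
            spectra.append(
                MSnSpectrum(
                    dataset_id=dataset_id,
                    spectrum_id=index,
                    scan=scan,
                    ms_level=2,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    peaks=peaks,
                )
            )
    return spectra


def _extract_scan(params: dict, index: int) -> int:
    if "scans" in params:
        return int(str(params["scans"]).split("-")[0])
    title = str(params.get("title", ""))
    m = _SCAN_RE.search(title)
    if m:
        return int(m.group(1))
    return index + 1


def _read_mzxml(path: Path, dataset_id: str) -> list[MSnSpectrum]:
    spectra = []
    with _mzxml.MzXML(str(path)) as reader:
        for index, entry in enumerate(reader):
            level = int(entry.get("msLevel", 1))
            if level < 2:
                continue
            precursors = entry.get("precursorMz")
            if not precursors:
                logger.warning("%s: MSn scan %s has no precursor m/z; skipped",
                               path, entry.get("num"))
                continue
            prec = precursors[0]
            charge = int(prec.get("precursorCharge", 0) or 0)
            peaks = np.column_stack(
                [np.asarray(entry["m/z array"], float), np.asarray(entry["intensity array"], float)]
            )
            spectra.append(
                MSnSpectrum(
                    dataset_id=dataset_id,
                    spectrum_id=index,
                    scan=int(entry["num"]),
                    ms_level=level,
                    precursor_mz=float(prec["precursorMz"]),
                    precursor_charge=charge,
                    peaks=peaks,
                )
            )
    return spectra


def write_mgf(spectra, path, titles: list[str] | None = None) -> None:
    """Write spectra to MGF; ``titles`` overrides the per-spectrum TITLE."""
    entries = []
    for i, s in enumerate(spectra):
        title = titles[i] if titles else f"dataset={s.dataset_id} scan={s.scan} id={s.spectrum_id}"
        params = {"title": title, "pepmass": s.precursor_mz, "scans": str(s.scan)}
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        entries.append(
            {
                "params": params,
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# AMT-tag reference tables
# ---------------------------------------------------------------------------

_AMT_ALIASES = {
    "sequence": ("sequence", "peptide", "peptide_sequence"),
    "monoisotopic_mass": ("monoisotopic_mass", "monoisotopic_mw", "mass", "mono_mass"),
    "net": ("net", "avg_net", "net_avg", "normalized_elution_time"),
}


def read_amt_tags(path) -> list[AMTTag]:
    """Read an AMT-tag table from CSV or a SQLite ``amt_tags`` table.

    Rows with NET outside [0, 1] are rejected with a warning.  Duplicate
    (sequence, mass) rows collapse to a single tag keeping the mean NET.
    """
    path = Path(path)
    if path.suffix.lower() in (".db", ".db3", ".sqlite", ".sqlite3"):
        con = sqlite3.connect(path)
        try:
            frame = pd.read_sql_query("SELECT * FROM amt_tags", con)
        finally:
            con.close()
    else:
        frame = pd.read_csv(path, skipinitialspace=True)

    lower = {c.strip().lower(): c for c in frame.columns}
    resolved = {}
    for canonical, names in _AMT_ALIASES.items():
        for name in names:
            if name in lower:
                resolved[canonical] = lower[name]
                break
        else:
            raise FormatError(f"AMT table missing required column {canonical!r}")
    obs_col = next((lower[n] for n in ("observation_count", "obs_count") if n in lower), None)

    rows = []
    for _, row in frame.iterrows():
        net = float(row[resolved["net"]])
        if not 0.0 <= net <= 1.0:
            logger.warning("AMT row with NET %.4f outside [0, 1] rejected", net)
            continue
        rows.append(
            (
                str(row[resolved["sequence"]]),
                float(row[resolved["monoisotopic_mass"]]),
                net,
                int(row[obs_col]) if obs_col is not None else 1,
            )
        )

    # collapse duplicates on (sequence, mass) keeping mean NET
    grouped: dict[tuple[str, float], list] = {}
    order: list[tuple[str, float]] = []
    for seq, mass, net, obs in rows:
        key = (seq, mass)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((net, obs))
    tags = []
    for i, key in enumerate(order):
        seq, mass = key
        nets = [n for n, _ in grouped[key]]
        obs = sum(o for _, o in grouped[key])
        tags.append(
            AMTTag(
                tag_id=f"T{i}",
                sequence=seq,
                monoisotopic_mass=mass,
                net=float(np.mean(nets)),
                observation_count=obs,
            )
        )
    return tags


def write_amt_tags(tags: list[AMTTag], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence", "monoisotopic_mass", "net", "observation_count"])
        for t in tags:
            writer.writerow([t.sequence, repr(t.monoisotopic_mass), repr(t.net), t.observation_count])


# ---------------------------------------------------------------------------
# cross-tab cluster CSV
# ---------------------------------------------------------------------------


def write_crosstab(clusters: list[FeatureCluster], dataset_order: list[str], path) -> None:
    """Write the cluster cross-tab: one row per cluster, one abundance
    column per dataset (empty cell = the cluster has no member there)."""
    known = set(dataset_order)
    for c in clusters:
        for m in c.members:
            if m.dataset_id not in known:
                raise ValueError(f"cluster {c.cluster_id} member dataset "
                                 f"{m.dataset_id!r} not in dataset_order")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cluster_id", "centroid_mass", "centroid_net", "tightness", "ambiguity",
             "member_count"] + [f"abundance_{d}" for d in dataset_order]
        )
        for c in clusters:
            per_dataset: dict[str, float] = {}
            for m in c.members:
                per_dataset[m.dataset_id] = per_dataset.get(m.dataset_id, 0.0) + m.abundance
            row = [
                c.cluster_id,
                repr(c.centroid_mass),
                repr(c.centroid_net),
                repr(c.tightness),
                "inf" if math.isinf(c.ambiguity) else repr(c.ambiguity),
                c.member_count,
            ]
            row += ["" if d not in per_dataset else repr(per_dataset[d]) for d in dataset_order]
            writer.writerow(row)


def read_crosstab(path) -> pd.DataFrame:
    """Parse a cross-tab back into a DataFrame (abundances NaN when absent)."""
    frame = pd.read_csv(path)
    for col in frame.columns:
        if col.startswith("abundance_") or col == "ambiguity":
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame


def write_score_matrix(matrix: np.ndarray, path) -> None:
    """Export an alignment section-score matrix (heat-map data) as CSV."""
    np.savetxt(path, np.asarray(matrix, float), delimiter=",", fmt="%.6g")
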