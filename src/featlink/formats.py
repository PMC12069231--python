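"""Readers and writers for every external artifact.

Feature tables come from peak pickers such as XCMS or MZmine as CSV/TSV
exports whose column naming varies; the reader recognises common aliases for
the id, m/z and retention-time columns and treats everything else numeric as
a sample intensity column.  The canonical retention-time unit is seconds:
the ``mzmine`` dialect stores minutes and is converted, and ``auto`` falls
back to a heuristic (all rt below 60 looks like minutes and triggers a
warning).

MS2 spectra are read from mzML, mzXML or MGF through pyteomics; only
MS-level-2 scans are returned.  Adduct and neutral-loss rule tables are
plain CSV, with bundled defaults used when no path is given.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AdductRule,
    AnnotationEdge,
    Feature,
    FeatureTable,
    FormatError,
    MS2Spectrum,
    NeutralLossEntry,
    TargetMetabolite,
    ValidationError,
)

__all__ = [
    "read_feature_table",
    "read_targets",
    "read_ms2",
    "read_rule_tables",
    "AnnotatedFeatureTable",
    "write_annotated_table",
    "write_network",
    "ANNOTATION_COLUMNS",
]

# Column-header aliases, matched case-insensitively after stripping.
_ID_ALIASES = {"feature", "feature_id", "featureid", "id", "name", "row id", "row.id", "peak_id"}
_MZ_ALIASES = {"mz", "m/z", "mzmed", "row m/z", "row.mz", "mz_med", "mass"}
_RT_ALIASES = {"rt", "retention_time", "retention time", "rtmed", "row retention time",
               "row.rt", "rt_med"}
#: Annotation columns written by this package, in output order.
ANNOTATION_COLUMNS = [
    "target", "adduct", "isotope", "charge", "neutral_loss", "isf_parent",
    "group", "corgroup", "group_intersect", "group_union",
]
# Non-intensity columns silently ignored on read (XCMS/MZmine/our own output).
_OTHER_META = {
    "mzmin", "mzmax", "rtmin", "rtmax", "npeaks", "isotopes", "adduct", "pcgroup",
    "compound", "identity", "fold", "tstat", "pvalue",
} | set(ANNOTATION_COLUMNS)


def _normalize(col: str) -> str:
    return col.strip().lower()


def read_feature_table(
    path: str | Path,
    dialect: str = "auto",
    intensity_columns: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """Read an XCMS/MZmine-style MS1 feature table from CSV or TSV.

    Parameters
    ----------
    path : path
        Delimiter is sniffed (comma or tab).
    dialect : {"auto", "xcms", "mzmine"}
        Controls the retention-time unit: ``xcms`` tables store seconds,
        ``mzmine`` minutes (converted x60).  With ``auto``, values whose
        maximum is below 60 are assumed to be minutes (with a warning).
    intensity_columns : sequence of str, optional
        Explicit sample-column names; otherwise every column not recognised
        as metadata is an intensity column.
    """
    path = Path(path)
    if dialect not in ("auto", "xcms", "mzmine"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")

    norm = {_normalize(c): c for c in df.columns}
    mz_col = next((norm[a] for a in _MZ_ALIASES if a in norm), None)
    if mz_col is None:
        raise FormatError(
            f"{path}: no m/z column found (looked for {sorted(_MZ_ALIASES)})"
        )
    id_col = next((norm[a] for a in _ID_ALIASES if a in norm), None)
    rt_col = next((norm[a] for a in _RT_ALIASES if a in norm), None)

    mz = pd.to_numeric(df[mz_col], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(mz.to_numpy()))
    if bad.size:
        raise FormatError(
            f"{path}: non-numeric m/z in data row(s) {bad.tolist()[:10]}"
        )

    if rt_col is not None:
        rt = pd.to_numeric(df[rt_col], errors="coerce").to_numpy(dtype=float)
        finite = rt[np.isfinite(rt)]
        if dialect == "mzmine":
            rt = rt * 60.0
        elif dialect == "auto" and finite.size and finite.max() < 60:
            warnings.warn(
                f"{path}: all retention times < 60; assuming minutes and "
                "converting to seconds (pass dialect='xcms' to suppress)",
                stacklevel=2,
            )
            rt = rt * 60.0
    else:
        rt = np.full(len(df), np.nan)

    if id_col is not None:
        ids = df[id_col].astype(str).str.strip().tolist()
    else:
        ids = [f"F{i + 1}" for i in range(len(df))]
    dupes = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dupes:
        raise ValidationError(f"{path}: duplicate feature ids: {dupes}")

    meta_cols = {mz_col, id_col, rt_col} - {None}
    if intensity_columns is not None:
        missing = [c for c in intensity_columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: intensity columns not found: {missing}")
        sample_cols = list(intensity_columns)
    else:
        sample_cols = [
            c for c in df.columns
            if c not in meta_cols and _normalize(c) not in _OTHER_META
        ]
    if not sample_cols:
        raise FormatError(f"{path}: no intensity columns detected")
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    features = [
        Feature(
            id=ids[i],
            mz=float(mz.iloc[i]),
            rt=None if not np.isfinite(rt[i]) else float(rt[i]),
            intensities=inten[i],
        )
        for i in range(len(df))
    ]
    return FeatureTable(features=features, sample_names=sample_cols)


def read_targets(path: str | Path) -> list[TargetMetabolite]:
    """Read a target metabolite list: columns name, formula, optional rt (s)."""
    df = pd.read_csv(Path(path), sep=None, engine="python")
    norm = {_normalize(c): c for c in df.columns}
    name_col = next((norm[a] for a in ("name", "metabolite", "compound")), None)
    formula_col = next((norm[a] for a in ("formula", "molecular_formula")), None)
    if name_col is None or formula_col is None:
        raise FormatError(f"{path}: target list needs 'name' and 'formula' columns")
    rt_col = next((norm[a] for a in _RT_ALIASES if a in norm), None)
    targets = []
    for _, row in df.iterrows():
        rt = None
        if rt_col is not None and pd.notna(row[rt_col]):
            rt = float(row[rt_col])
        targets.append(
            TargetMetabolite(name=str(row[name_col]), formula=str(row[formula_col]).strip(), rt=rt)
        )
    return targets


def _rt_seconds(value, unit_info) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    if unit_info == "minute":
        v *= 60.0
    return v


def read_ms2(path: str | Path) -> list[MS2Spectrum]:
    """Read MS-level-2 spectra from an mzML, mzXML or MGF file.

    The format is detected from the file extension.  Peaks come back sorted
    by ascending fragment m/z; a spectrum without a recorded retention time
    keeps ``precursor_rt=None``.  A file with no MS2 scans yields an empty
    list with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    spectra: list[MS2Spectrum] = []
    if suffix == ".mgf":
        from pyteomics import mgf

        with mgf.MGF(str(path)) as reader:
            for spec in reader:
                params = spec.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None:
                    continue
                prec_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                rt = params.get("rtinseconds")
                prec_rt = float(rt) if rt is not None else None
                peaks = np.column_stack(
                    [np.asarray(spec["m/z array"], float), np.asarray(spec["intensity array"], float)]
                )
                spectra.append(
                    MS2Spectrum(prec_mz, prec_rt, peaks, title=str(params.get("title", "")))
                )
    elif suffix == ".mzml":
        spectra.extend(_read_mzml(path))
    elif suffix == ".mzxml":
        from pyteomics import mzxml

        with mzxml.MzXML(str(path)) as reader:
            for spec in reader:
                if int(spec.get("msLevel", 1)) != 2:
                    continue
                prec_list = spec.get("precursorMz")
                if not prec_list:
                    continue
                entry = prec_list[0]
                prec_mz = float(entry["precursorMz"] if isinstance(entry, dict) else entry)
                t = spec.get("retentionTime")
                prec_rt = _rt_seconds(t, getattr(t, "unit_info", None)) if t is not None else None
                peaks = np.column_stack(
                    [np.asarray(spec["m/z array"], float), np.asarray(spec["intensity array"], float)]
                )
                spectra.append(MS2Spectrum(prec_mz, prec_rt, peaks, title=str(spec.get("num", ""))))
    else:
        raise FormatError(f"{path}: unsupported MS2 format {suffix!r} (use .mzML, .mzXML or .mgf)")
    if not spectra:
        warnings.warn(f"{path}: no MS2 spectra found", stacklevel=2)
    return spectra


def _read_mzml(path: Path) -> list[MS2Spectrum]:
    """Minimal mzML 1.1 reader: MS2 scans with precursor m/z, rt and peaks.

    Streams ``<spectrum>`` elements with ElementTree, decoding 64/32-bit
    float binary arrays with optional zlib compression.  Covers the
    centroided single-precursor spectra DDA pool files contain.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    def decode_array(bda) -> np.ndarray:
        dtype, compressed, text = "<f8", False, None
        for child in bda.iter():
            if local(child.tag) == "cvParam":
                acc = child.get("accession", "")
                if acc == "MS:1000521":
                    dtype = "<f4"
                elif acc == "MS:1000574":
                    compressed = True
            elif local(child.tag) == "binary":
                text = child.text or ""
        raw = base64.b64decode(text or "")
        if compressed:
            raw = zlib.decompress(raw)
        return np.frombuffer(raw, dtype=dtype).astype(float)

    out: list[MS2Spectrum] = []
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if local(elem.tag) != "spectrum":
                continue
            ms_level = prec_mz = prec_rt = None
            arrays: dict[str, np.ndarray] = {}
            for child in elem.iter():
                tag = local(child.tag)
                if tag == "cvParam":
                    acc = child.get("accession", "")
                    if acc == "MS:1000511":
                        ms_level = int(child.get("value", "0"))
                    elif acc == "MS:1000744":
                        prec_mz = float(child.get("value"))
                    elif acc == "MS:1000016":
                        prec_rt = _rt_seconds(
                            float(child.get("value")),
                            "minute" if child.get("unitName", "").startswith("min") else "second",
                        )
                elif tag == "binaryDataArray":
                    kind = None
                    for cv in child.iter():
                        if local(cv.tag) == "cvParam":
                            if cv.get("accession") == "MS:1000514":
                                kind = "mz"
                            elif cv.get("accession") == "MS:1000515":
                                kind = "intensity"
                    if kind:
                        arrays[kind] = decode_array(child)
            if ms_level == 2 and prec_mz is not None and "mz" in arrays and "intensity" in arrays:
                peaks = np.column_stack([arrays["mz"], arrays["intensity"]])
                out.append(MS2Spectrum(prec_mz, prec_rt, peaks, title=str(elem.get("id", ""))))
            elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed mzML: {exc}") from exc
    return out


def _bundled(name: str) -> Path:
    return Path(str(importlib.resources.files("featlink").joinpath("data", name)))


def read_rule_tables(
    adduct_path: Optional[str | Path] = None,
    nl_path: Optional[str | Path] = None,
) -> tuple[list[AdductRule], list[NeutralLossEntry]]:
    """Load adduct and neutral-loss rule tables, falling back to bundled defaults.

    The adduct CSV needs columns (name, ion_mode, multiplicity, charge,
    mass_shift); the neutral-loss CSV (name, formula, mass).  Malformed
    masses and unknown ion-mode tokens raise row-level errors.
    """
    apath = Path(adduct_path) if adduct_path is not None else _bundled("adducts.csv")
    npath = Path(nl_path) if nl_path is not None else _bundled("neutral_losses.csv")

    adf = pd.read_csv(apath)
    rules: list[AdductRule] = []
    for i, row in adf.iterrows():
        try:
            rules.append(
                AdductRule(
                    name=str(row["name"]).strip(),
                    ion_mode=str(row["ion_mode"]).strip().lower(),
                    multiplicity=int(row["multiplicity"]),
                    charge=int(row["charge"]),
                    mass_shift=float(row["mass_shift"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{apath}: bad adduct rule in row {i}: {exc}") from exc

    ndf = pd.read_csv(npath)
    losses: list[NeutralLossEntry] = []
    for i, row in ndf.iterrows():
        try:
            mass = float(row["mass"])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{npath}: bad neutral-loss mass in row {i}") from exc
        formula = row.get("formula")
        entry_formula = None if pd.isna(formula) else str(formula).strip()
        try:
            losses.append(NeutralLossEntry(name=str(row["name"]).strip(), mass=mass,
                                           formula=entry_formula))
        except ValidationError as exc:
            raise ValidationError(f"{npath}: row {i}: {exc}") from exc
    return rules, losses


@dataclass
class AnnotatedFeatureTable:
    """A feature table plus one row of annotation strings per feature.

    ``annotations`` is a DataFrame indexed by feature id with the columns in
    :data:`ANNOTATION_COLUMNS`; absent annotations are empty strings (never
    "NA", which could collide with adduct shorthand).
    """

    table: FeatureTable
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        for c in missing:
            self.annotations[c] = ""
        self.annotations = self.annotations.reindex(self.table.ids).fillna("")

    def to_dataframe(self) -> pd.DataFrame:
        t = self.table
        df = pd.DataFrame({"feature": t.ids, "mz": t.mz_array(), "rt": t.rt_array()})
        inten = t.intensity_matrix()
        for j, s in enumerate(t.sample_names):
            df[s] = inten[:, j]
        for c in ANNOTATION_COLUMNS:
            df[c] = self.annotations[c].to_numpy()
        return df


def write_annotated_table(table: AnnotatedFeatureTable, path: str | Path) -> None:
    """Write the annotated table as CSV; numeric fields round-trip exactly."""
    df = table.to_dataframe()
    df.to_csv(Path(path), index=False, float_format=None)


def write_network(
    edges: Iterable[AnnotationEdge],
    path: str | Path,
    format: str = "edgelist",
) -> None:
    """Export relation/correlation edges as an edge-list CSV or GraphML.

    The edge list has columns (source, target, relation, detail, mz_diff,
    correlation).  GraphML is written through networkx and loads in standard
    graph tools; parallel edges of different relation types are preserved.
    """
    path = Path(path)
    edges = list(edges)
    if format == "edgelist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "relation", "detail", "mz_diff", "correlation"])
            for e in edges:
                writer.writerow([
                    e.source_id, e.target_id, e.relation, e.detail,
                    repr(float(e.mz_diff)),
                    "" if e.correlation is None else repr(float(e.correlation)),
                ])
    elif format == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for e in edges:
            attrs = {"relation": e.relation, "detail": e.detail, "mz_diff": float(e.mz_diff)}
            if e.rt_diff is not None:
                attrs["rt_diff"] = float(e.rt_diff)
            if e.correlation is not None:
                attrs["correlation"] = float(e.correlation)
            g.add_edge(e.source_id, e.target_id, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r} (use 'edgelist' or 'graphml')")
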