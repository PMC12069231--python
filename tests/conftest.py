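"""Shared fixtures: tiny feature tables and a minimal mzML writer."""

from __future__ import annotations

import base64
import struct

import numpy as np
import pytest
from hypothesis import settings

from featlink import Feature, FeatureTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(rows, samples=("s1", "s2", "s3")):
    """Build a FeatureTable from (id, mz, rt, intensities) tuples.

    ``intensities`` may be omitted (filled with 1000s) or shorter than the
    sample panel (padded with NaN is *not* done — lengths must match).
    """
    feats = []
    for row in rows:
        if len(row) == 3:
            fid, mz, rt = row
            inten = np.full(len(samples), 1000.0)
        else:
            fid, mz, rt, inten = row
            inten = np.asarray(inten, dtype=float)
        feats.append(Feature(id=fid, mz=mz, rt=rt, intensities=inten))
    return FeatureTable(features=feats, sample_names=list(samples))


@pytest.fixture
def small_table():
    return make_table(
        [
            ("a", 181.0707, 120.0, (10.0, 100.0, 1000.0)),
            ("b", 203.0526, 121.0, (20.0, 200.0, 2000.0)),
            ("c", 435.1291, 200.0, (5.0, 50.0, 500.0)),
        ]
    )


def _b64(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *[float(v) for v in values])
    return base64.b64encode(raw).decode("ascii")


def _spectrum_xml(index: int, spec: dict) -> str:
    mzs = list(spec["mz_array"])
    intens = list(spec["intensity_array"])
    ms_level = spec.get("ms_level", 2)
    rt_min = spec.get("rt_seconds")
    parts = [
        f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
    ]
    if rt_min is not None:
        parts.append(
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt_min / 60.0}" unitAccession="UO:0000031" unitName="minute"/>'
            "</scan></scanList>"
        )
    if ms_level == 2:
        parts.append(
            '<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{spec["precursor_mz"]}"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
        )
    for accession, name, values in (
        ("MS:1000514", "m/z array", mzs),
        ("MS:1000515", "intensity array", intens),
    ):
        payload = _b64(values)
        parts.append(
            f'<binaryDataArray encodedLength="{len(payload)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>'
            f"<binary>{payload}</binary></binaryDataArray>"
        )
    parts.append("</spectrum>")
    return "".join(parts)


def write_mzml(path, spectra: list[dict]) -> None:
    """Write a minimal mzML 1.1 file.

    Each spectrum dict carries ``mz_array``, ``intensity_array``,
    ``ms_level`` (default 2), optional ``precursor_mz`` (MS2 only) and
    optional ``rt_seconds``.
    """
    body = "".join(_spectrum_xml(i, s) for i, s in enumerate(spectra))
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="1">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        "</cvList>"
        '<run id="run1">'
        f'<spectrumList count="{len(spectra)}">{body}</spectrumList>'
        "</run></mzML>"
    )
    with open(path, "w") as fh:
        fh.write(doc)
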