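"""Minimal mzML support: MS2 spectrum extraction and a fixture writer.

Only what the pipeline needs is implemented: iterating centroided spectra,
decoding m/z + intensity binary arrays (64/32-bit floats, optional zlib),
reading the scan start time (normalized to seconds at read time) and the
selected-ion precursor m/z.  Profile-mode spectra and MS2 scans without a
precursor are skipped, with counts reported.
"""

from __future__ import annotations

import base64
import os
import struct
import warnings
import xml.etree.ElementTree as ET
import zlib

from ..errors import FormatError
from ..models import MSSpectrum

# PSI-MS controlled vocabulary accessions
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _local(tag):
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem):
    out = {}
    for child in elem.iter():
        if _local(child.tag) == "cvParam":
            out.setdefault(child.get("accession"), child)
    return out


def _decode_binary_array(bda):
    accs = {
        c.get("accession")
        for c in bda.iter()
        if _local(c.tag) == "cvParam"
    }
    text = ""
    for c in bda.iter():
        if _local(c.tag) == "binary":
            text = (c.text or "").strip()
    data = base64.b64decode(text) if text else b""
    if _ACC_ZLIB in accs and data:
        data = zlib.decompress(data)
    fmt = "d" if _ACC_F64 in accs or _ACC_F32 not in accs else "f"
    n = len(data) // struct.calcsize(fmt)
    values = struct.unpack("<" + fmt * n, data[: n * struct.calcsize(fmt)])
    kind = "mz" if _ACC_MZ_ARRAY in accs else ("intensity" if _ACC_INT_ARRAY in accs else None)
    return kind, list(values)


def extract_ms2_from_mzml(path):
    """Extract all centroided MS2 spectra from an mzML file.

    Returns ``(spectra, n_skipped)`` where skipped counts profile-mode MS2
    scans and MS2 scans without a selected-ion precursor.  MS1 scans are
    ignored.  Retention times encoded in minutes are converted to seconds.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise FormatError(f"{path}: not valid mzML ({e})")
    spectra = []
    n_skipped = 0
    for spec in tree.getroot().iter():
        if _local(spec.tag) != "spectrum":
            continue
        params = {}
        for child in list(spec):
            if _local(child.tag) == "cvParam":
                params[child.get("accession")] = child
        level_param = params.get(_ACC_MS_LEVEL)
        ms_level = int(level_param.get("value")) if level_param is not None else 1
        if ms_level < 2:
            continue
        if _ACC_PROFILE in params:
            n_skipped += 1
            continue
        rt = None
        precursor_mz = None
        mzs, intens = [], []
        for node in spec.iter():
            tag = _local(node.tag)
            if tag == "cvParam" and node.get("accession") == _ACC_SCAN_START:
                rt = float(node.get("value"))
                unit = (node.get("unitName") or "").lower()
                if unit.startswith("min"):
                    rt *= 60.0
            elif tag == "cvParam" and node.get("accession") == _ACC_SELECTED_MZ:
                precursor_mz = float(node.get("value"))
            elif tag == "binaryDataArray":
                kind, values = _decode_binary_array(node)
                if kind == "mz":
                    mzs = values
                elif kind == "intensity":
                    intens = values
        if precursor_mz is None:
            n_skipped += 1
            continue
        spectra.append(
            MSSpectrum(
                peaks=list(zip(mzs, intens)),
                ms_level=ms_level,
                precursor_mz=precursor_mz,
                retention_time=rt,
                source_acquisition=os.path.basename(str(path)),
            )
        )
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} MS2 spectra (profile mode or no precursor)")
    return spectra, n_skipped


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def _encode_array(values, kind):
    data = struct.pack("<" + "d" * len(values), *[float(v) for v in values])
    b64 = base64.b64encode(data).decode("ascii")
    acc = _ACC_MZ_ARRAY if kind == "mz" else _ACC_INT_ARRAY
    name = "m/z array" if kind == "mz" else "intensity array"
    return (
        f'<binaryDataArray encodedLength="{len(b64)}">'
        f'<cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float"/>'
        f'<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}"/>'
        f"<binary>{b64}</binary></binaryDataArray>"
    )


def write_mzml(spectra, path, rt_unit: str = "second"):
    """Write a minimal centroided mzML file (used for fixtures and demos).

    ``rt_unit`` may be "second" or "minute"; values are converted so the file
    is self-consistent with its declared unit.
    """
    if rt_unit not in ("second", "minute"):
        raise FormatError(f"unsupported rt unit {rt_unit!r}")
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "<run id=\"run1\">",
        f'<spectrumList count="{len(spectra)}">',
    ]
    for i, s in enumerate(spectra):
        rt = s.retention_time or 0.0
        if rt_unit == "minute":
            rt = rt / 60.0
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s.peaks)}">'
        )
        parts.append(
            f'<cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="{s.ms_level}"/>'
        )
        parts.append('<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>')
        parts.append(
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" '
            f'value="{rt!r}" unitName="{rt_unit}"/>'
            "</scan></scanList>"
        )
        if s.ms_level >= 2 and s.precursor_mz is not None:
            parts.append(
                '<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="{_ACC_SELECTED_MZ}" name="selected ion m/z" '
                f'value="{s.precursor_mz!r}"/>'
                "</selectedIon></selectedIonList></precursor></precursorList>"
            )
        parts.append('<binaryDataArrayList count="2">')
        parts.append(_encode_array([p[0] for p in s.peaks], "mz"))
        parts.append(_encode_array([p[1] for p in s.peaks], "intensity"))
        parts.append("</binaryDataArrayList></spectrum>")
    parts.append("</spectrumList></run></mzML>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
    return path
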