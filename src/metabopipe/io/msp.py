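"""MSP spectral library parsing and writing.

The MSP text format (as distributed e.g. by MoNA) is a sequence of entries:

    Name: compound
    PrecursorMZ: 181.0707
    Formula: C6H12O6
    Num Peaks: 3
    85.0284 100
    97.0284 50
    127.039 10

Entries whose declared ``Num Peaks`` disagrees with the actual pair count are
skipped with a warning; entries lacking a precursor m/z are retained but are
not indexable by precursor.
"""

from __future__ import annotations

import re
import warnings

from ..annotation.types import RefSpectrum

_PRECURSOR_KEYS = ("precursormz", "precursor_mz", "precursor m/z", "precursortype_mz")
_PEAK_RE = re.compile(r"^\s*([0-9.eE+-]+)[\s;,]+([0-9.eE+-]+)")


def read_msp_library(path, source_library=None, is_authentic_standard=False):
    """Parse an MSP file into a list of :class:`RefSpectrum`."""
    if source_library is None:
        # base name only: keeps records stable across directory layouts
        import os

        source_library = os.path.basename(str(path))
    entries = []
    current = None

    def flush(entry):
        if entry is None:
            return
        declared = entry.get("num_peaks")
        peaks = entry["peaks"]
        if declared is not None and declared != len(peaks):
            warnings.warn(
                f"{path}: entry {entry.get('name', '?')!r} declares "
                f"{declared} peaks but has {len(peaks)}; skipped"
            )
            return
        entries.append(
            RefSpectrum(
                compound_name=entry.get("name", ""),
                precursor_mz=entry.get("precursor_mz"),
                peaks=peaks,
                source_library=source_library,
                is_authentic_standard=is_authentic_standard,
                formula=entry.get("formula", ""),
                identifiers=entry.get("identifiers", {}),
            )
        )

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush(current)
                current = None
                continue
            if ":" in line and not _PEAK_RE.match(line):
                key, _, value = line.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "name":
                    flush(current)
                    current = {"name": value, "peaks": [], "identifiers": {}}
                elif current is None:
                    continue
                elif key in _PRECURSOR_KEYS:
                    try:
                        current["precursor_mz"] = float(value)
                    except ValueError:
                        pass
                elif key == "formula":
                    current["formula"] = value
                elif key == "num peaks":
                    try:
                        current["num_peaks"] = int(value)
                    except ValueError:
                        pass
                elif key in ("inchikey", "casno", "db#", "smiles"):
                    current["identifiers"][key] = value
            else:
                m = _PEAK_RE.match(line)
                if m and current is not None:
                    current["peaks"].append((float(m.group(1)), float(m.group(2))))
    flush(current)
    return entries


def write_msp_library(refs, path):
    """Write reference spectra as MSP text (round-trips through the reader)."""
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f"Name: {r.compound_name}\n")
            if r.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {r.precursor_mz!r}\n")
            if r.formula:
                fh.write(f"Formula: {r.formula}\n")
            fh.write(f"Num Peaks: {len(r.peaks)}\n")
            for mz, inten in r.peaks:
                fh.write(f"{mz!r} {inten!r}\n")
            fh.write("\n")
    return path
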