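"""Sample metadata CSV I/O.

The metadata CSV minimally maps sample names to acquisition file paths;
optional ``sample_type`` (study/blank/pool/standard) and ``batch`` columns
default to ``study`` and ``"1"``.  Extra columns are preserved as arbitrary
acquisition metadata.
"""

from __future__ import annotations

import csv

from ..errors import FormatError
from ..models import Acquisition

_NAME_ALIASES = ("name", "sample", "sample_name")
_PATH_ALIASES = ("filepath", "file_path", "path", "file")
_TYPE_ALIASES = ("sample_type", "type")
_BATCH_ALIASES = ("batch", "batch_id")
_KNOWN_TYPES = ("study", "blank", "pool", "standard")


def _pick(header, aliases):
    lower = {h.lower(): h for h in header}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def read_sample_metadata(path):
    """Read a metadata CSV into a list of :class:`Acquisition`."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise FormatError(f"{path}: empty metadata file")
    header = list(rows[0].keys())
    name_col = _pick(header, _NAME_ALIASES)
    path_col = _pick(header, _PATH_ALIASES)
    if name_col is None or path_col is None:
        raise FormatError(
            f"{path}: need a sample-name column ({'/'.join(_NAME_ALIASES)}) "
            f"and a filepath column ({'/'.join(_PATH_ALIASES)})"
        )
    type_col = _pick(header, _TYPE_ALIASES)
    batch_col = _pick(header, _BATCH_ALIASES)
    known = {name_col, path_col, type_col, batch_col}

    acquisitions, seen, dupes = [], set(), []
    for row in rows:
        name = (row[name_col] or "").strip()
        if not name:
            continue
        if name in seen:
            dupes.append(name)
        seen.add(name)
        sample_type = (row.get(type_col) or "study").strip().lower() if type_col else "study"
        if sample_type not in _KNOWN_TYPES:
            raise FormatError(
                f"{path}: unknown sample_type {sample_type!r} for {name!r}; "
                f"expected one of {_KNOWN_TYPES}"
            )
        acquisitions.append(
            Acquisition(
                name=name,
                filepath=(row[path_col] or "").strip(),
                sample_type=sample_type,
                batch=str(row.get(batch_col) or "1").strip() if batch_col else "1",
                metadata={k: v for k, v in row.items() if k not in known},
            )
        )
    if dupes:
        raise FormatError(f"{path}: duplicate sample names: {sorted(set(dupes))}")
    if not acquisitions:
        raise FormatError(f"{path}: no samples found")
    return acquisitions


def write_sample_metadata(acquisitions, path):
    """Write acquisitions back to CSV (inverse of :func:`read_sample_metadata`)."""
    extra_keys = sorted({k for a in acquisitions for k in a.metadata})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample", "filepath", "sample_type", "batch"] + extra_keys)
        for a in acquisitions:
            writer.writerow(
                [a.name, a.filepath, a.sample_type, a.batch]
                + [a.metadata.get(k, "") for k in extra_keys]
            )
    return path
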