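"""Feature table TSV I/O.

Two dialects:

* ``asari`` — fixed leading metadata columns (``id_number``, ``mz``,
  ``rtime``, plus optional quality columns), remaining columns are samples.
* ``generic`` — caller names the id/mz/rtime columns; every other numeric
  column is a sample.

Missing intensity cells read as 0 (imputation is an explicit QC step);
non-numeric intensity cells are an error, never silently coerced.
"""

from __future__ import annotations

import csv
import math

from ..errors import FormatError
from ..models import Feature, FeatureTable

_ASARI_META = {
    "id_number": "id",
    "mz": "mz",
    "rtime": "rtime",
    "rtime_left_base": None,
    "rtime_right_base": None,
    "parent_masstrack_id": None,
    "peak_area": None,
    "cSelectivity": None,
    "goodness_fitting": "goodness_fit",
    "snr": "snr",
    "detection_counts": None,
}


def read_feature_table(
    path,
    dialect: str = "asari",
    id_col: str = "id",
    mz_col: str = "mz",
    rtime_col: str = "rtime",
    provenance_tag: str = "raw",
) -> FeatureTable:
    """Read a tab-separated feature table into a :class:`FeatureTable`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        rows = list(reader)

    if dialect == "asari":
        colmap = {"id_number": "id", "mz": "mz", "rtime": "rtime"}
        meta_cols = [c for c in header if c in _ASARI_META]
        required = ["id_number", "mz", "rtime"]
    elif dialect == "generic":
        colmap = {id_col: "id", mz_col: "mz", rtime_col: "rtime"}
        meta_cols = [c for c in header if c in colmap]
        required = [id_col, mz_col, rtime_col]
    else:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'asari' or 'generic'")

    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in header if c not in meta_cols]
    idx = {c: header.index(c) for c in header}

    features = []
    seen, dupes = set(), []
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        fid = row[idx[required[0]]].strip()
        if fid in seen:
            dupes.append(fid)
        seen.add(fid)
        try:
            mz = float(row[idx[required[1]]])
            rtime = float(row[idx[required[2]]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric mz/rtime for feature {fid!r}")
        intensities = {}
        for col in sample_cols:
            cell = row[idx[col]].strip() if idx[col] < len(row) else ""
            if cell == "" or cell.upper() in ("NA", "NAN"):
                value = 0.0
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric intensity {cell!r} "
                        f"in column {col!r}"
                    )
                if math.isnan(value):
                    value = 0.0
            intensities[col] = value
        extra = {}
        if dialect == "asari":
            for col, attr in _ASARI_META.items():
                if attr in ("snr", "goodness_fit") and col in idx:
                    try:
                        extra[attr] = float(row[idx[col]])
                    except (ValueError, IndexError):
                        pass
        features.append(
            Feature(
                id=fid, mz=mz, rtime=rtime, intensities=intensities,
                snr=extra.get("snr"), goodness_fit=extra.get("goodness_fit"),
            )
        )
    if dupes:
        raise FormatError(f"{path}: duplicate feature ids: {sorted(set(dupes))}")
    return FeatureTable(
        features=features, acquisitions=sample_cols, provenance_tag=provenance_tag
    )


def write_feature_table(table: FeatureTable, path, dialect: str = "generic"):
    """Write a feature table as TSV; inverse of :func:`read_feature_table`.

    Floats use repr so a read-back round-trips within 1e-9 relative.
    """
    id_header = "id_number" if dialect == "asari" else "id"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([id_header, "mz", "rtime"] + list(table.acquisitions))
        for f in table.features:
            row = [f.id, repr(f.mz), repr(f.rtime)]
            row += [repr(float(f.intensities.get(a, 0.0))) for a in table.acquisitions]
            writer.writerow(row)
    return path
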