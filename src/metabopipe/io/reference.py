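"""Readers for reference resources: compound lists and authentic standards."""

from __future__ import annotations

import csv
import json

from ..annotation.types import StandardEntry
from ..errors import FormatError
from ..models import Compound

_MASS_ALIASES = ("neutral_mono_mass", "neutral_mass", "monoisotopic_mass", "mass")


def read_compound_list(path):
    """Read a compound list (CSV or JSON array) into :class:`Compound` objects.

    Required fields: a name and a neutral monoisotopic mass; formula optional.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        rows = raw if isinstance(raw, list) else raw.get("compounds", [])
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise FormatError(f"{path}: empty compound list")
    out = []
    for i, row in enumerate(rows):
        lower = {str(k).lower(): v for k, v in row.items()}
        name = lower.get("name") or lower.get("compound_name") or ""
        mass = None
        for alias in _MASS_ALIASES:
            if lower.get(alias) not in (None, ""):
                mass = float(lower[alias])
                break
        if mass is None:
            raise FormatError(f"{path}: entry {i} lacks a neutral mass column "
                              f"({'/'.join(_MASS_ALIASES)})")
        out.append(
            Compound(
                id=str(lower.get("id") or name),
                name=str(name),
                formula=str(lower.get("formula") or ""),
                neutral_mono_mass=mass,
            )
        )
    return out


def read_standards(path):
    """Read an authentic-standards CSV (name, mz, rtime, extra id columns)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise FormatError(f"{path}: empty standards file")
    out = []
    for i, row in enumerate(rows):
        lower = {str(k).lower(): v for k, v in row.items()}
        name = lower.get("name") or lower.get("compound_name")
        if not name or lower.get("mz") in (None, "") or lower.get("rtime") in (None, ""):
            raise FormatError(f"{path}: entry {i} needs name, mz and rtime")
        ids = {
            k: v
            for k, v in lower.items()
            if k not in ("name", "compound_name", "mz", "rtime") and v
        }
        out.append(
            StandardEntry(
                compound_name=str(name),
                mz=float(lower["mz"]),
                rtime=float(lower["rtime"]),
                identifiers=ids,
            )
        )
    return out
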