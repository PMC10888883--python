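"""Standardized three-table export.

The pipeline's final output is (1) a feature table TSV of m/z, RT and
per-acquisition intensities keyed by feature id, (2) an annotation table TSV
with one row per (feature, annotation) pair — multiple annotations per
feature appear as multiple rows — and (3) a sample table CSV of acquisition
and experiment metadata.  Referential integrity between the three tables is
checked on every export.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from ..errors import PipelineError
from .feature_table import write_feature_table
from .metadata import write_sample_metadata

ANNOTATION_COLUMNS = [
    "feature_id",
    "empcpd_id",
    "isotope",
    "modification",
    "level",
    "compound_name",
    "source",
    "score",
    "identifiers",
    "evidence",
]


@dataclass
class ThreeTableExport:
    feature_table_path: Path
    annotation_table_path: Path
    sample_table_path: Path


def export_three_tables(experiment, table_name, empcpd_set_name, out_dir):
    """Export the named table + empirical compound set as three linked tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = experiment.load_table(table_name)
    if empcpd_set_name is not None:
        empcpds = experiment.load_empcpd_set(empcpd_set_name)
    else:
        empcpds = []

    ft_path = out_dir / "feature_table.tsv"
    ann_path = out_dir / "annotation_table.tsv"
    sample_path = out_dir / "sample_table.csv"

    write_feature_table(table, ft_path)

    feature_ids = set(table.feature_ids())
    rows = []
    for ec in sorted(empcpds, key=lambda e: e.interim_id):
        for member in ec.ms1_features:
            if member.feature_id not in feature_ids:
                continue
            for ann in ec.annotations:
                rows.append(
                    [
                        member.feature_id,
                        ec.interim_id,
                        member.isotope,
                        member.modification,
                        ann.level,
                        ann.compound_name,
                        ann.source,
                        "" if ann.score is None else repr(ann.score),
                        ";".join(f"{k}={v}" for k, v in sorted(ann.identifiers.items())),
                        ";".join(f"{k}={v}" for k, v in sorted(ann.evidence.items())),
                    ]
                )
    with open(ann_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        writer.writerows(rows)

    acqs = [a for a in experiment.acquisitions if a.name in set(table.acquisitions)]
    write_sample_metadata(acqs, sample_path)

    export = ThreeTableExport(ft_path, ann_path, sample_path)
    violations = check_referential_integrity(export)
    if violations:
        raise PipelineError("three-table export failed integrity check: " + "; ".join(violations))
    return export


def check_referential_integrity(export: ThreeTableExport):
    """Verify the cross-table invariants; returns a list of violations."""
    violations = []
    with open(export.feature_table_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        feature_ids = {row[0] for row in reader if row}
    acq_cols = [c for c in header if c not in ("id", "id_number", "mz", "rtime")]
    with open(export.annotation_table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["feature_id"] not in feature_ids:
                violations.append(
                    f"annotation references unknown feature {row['feature_id']!r}"
                )
    with open(export.sample_table_path, newline="") as fh:
        sample_names = {row["sample"] for row in csv.DictReader(fh)}
    for col in acq_cols:
        if col not in sample_names:
            violations.append(f"feature table column {col!r} missing from sample table")
    return violations
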