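"""Markdown summary report for an experiment.

Covers the acquisition summary, per-stage feature counts, QC metrics,
annotation counts by level, and the full command timeline.
"""

from __future__ import annotations

from pathlib import Path

from .errors import PipelineError
from .models import ANNOTATION_LEVELS


def generate_report(experiment, out_path=None):
    if not experiment.feature_tables:
        raise PipelineError("report requires at least one feature table")
    lines = ["# Experiment report", ""]

    lines.append("## Acquisitions")
    lines.append("")
    lines.append("| name | type | batch |")
    lines.append("|---|---|---|")
    for a in experiment.acquisitions:
        lines.append(f"| {a.name} | {a.sample_type} | {a.batch} |")
    lines.append("")

    lines.append("## Feature tables")
    lines.append("")
    lines.append("| name | features | acquisitions |")
    lines.append("|---|---|---|")
    for name in sorted(experiment.feature_tables):
        table = experiment.load_table(name)
        lines.append(f"| {name} | {len(table.features)} | {len(table.acquisitions)} |")
    lines.append("")

    qaqc_dir = experiment.root_dir / "qaqc"
    if qaqc_dir.exists():
        csvs = sorted(p.name for p in qaqc_dir.glob("*.csv"))
        if csvs:
            lines.append("## QC metrics files")
            lines.append("")
            lines.extend(f"- qaqc/{name}" for name in csvs)
            lines.append("")

    lines.append("## Annotation counts by level")
    lines.append("")
    counts = {lvl: 0 for lvl in ANNOTATION_LEVELS}
    for name in sorted(experiment.empcpd_sets):
        for ec in experiment.load_empcpd_set(name):
            for ann in ec.annotations:
                counts[ann.level] = counts.get(ann.level, 0) + 1
    lines.append("| level | count |")
    lines.append("|---|---|")
    for lvl in ANNOTATION_LEVELS:
        lines.append(f"| {lvl} | {counts[lvl]} |")
    lines.append("")

    lines.append("## Command timeline")
    lines.append("")
    for i, rec in enumerate(experiment.command_log, start=1):
        params = ", ".join(f"{k}={v}" for k, v in rec.get("parameters", {}).items())
        lines.append(f"{i}. `{rec['command']}` ({rec['timestamp']}) {params}")
    lines.append("")

    out_path = Path(out_path) if out_path else experiment.root_dir / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path
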