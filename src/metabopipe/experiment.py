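"""On-disk experiment workspace with chainable steps and provenance logging.

An experiment is a directory holding a ``manifest.json`` plus referenced
feature tables (TSV) and empirical compound sets (JSON).  Every analysis
starts by assembling an experiment from a metadata CSV; each subsequent step
reads named inputs from the manifest, writes outputs under new names
(copy-on-write — stored predecessors are never mutated), and appends a
command record.  Re-running the recorded sequence on the same inputs
reproduces the same stored tables byte for byte.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PipelineError
from .io.feature_table import read_feature_table, write_feature_table
from .io.metadata import read_sample_metadata
from .models import Acquisition, parse_empcpd_set, serialize_empcpd_set

MANIFEST = "manifest.json"


@dataclass
class Experiment:
    root_dir: Path
    acquisitions: list = field(default_factory=list)
    feature_tables: dict = field(default_factory=dict)  # name -> relative path
    empcpd_sets: dict = field(default_factory=dict)
    command_log: list = field(default_factory=list)
    _counters: dict = field(default_factory=dict)

    # -- persistence --------------------------------------------------------

    def save(self):
        manifest = {
            "acquisitions": [a.to_dict() for a in self.acquisitions],
            "feature_tables": dict(sorted(self.feature_tables.items())),
            "empcpd_sets": dict(sorted(self.empcpd_sets.items())),
            "command_log": self.command_log,
            "counters": self._counters,
        }
        (self.root_dir / MANIFEST).write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, root_dir):
        root_dir = Path(root_dir)
        manifest_path = root_dir / MANIFEST
        if not manifest_path.exists():
            raise PipelineError(f"{root_dir} is not an experiment (no {MANIFEST})")
        raw = json.loads(manifest_path.read_text())
        return cls(
            root_dir=root_dir,
            acquisitions=[Acquisition.from_dict(a) for a in raw["acquisitions"]],
            feature_tables=dict(raw.get("feature_tables", {})),
            empcpd_sets=dict(raw.get("empcpd_sets", {})),
            command_log=list(raw.get("command_log", [])),
            _counters=dict(raw.get("counters", {})),
        )

    # -- storage ------------------------------------------------------------

    def save_table(self, table, name):
        rel = f"tables/{name}.tsv"
        path = self.root_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, path)
        self.feature_tables[name] = rel
        return rel

    def load_table(self, name):
        if name not in self.feature_tables:
            raise PipelineError(
                f"no feature table {name!r}; available: {sorted(self.feature_tables)}"
            )
        return read_feature_table(
            self.root_dir / self.feature_tables[name],
            dialect="generic",
            provenance_tag=name,
        )

    def save_empcpd_set(self, empcpds, name):
        rel = f"empcpds/{name}.json"
        path = self.root_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(serialize_empcpd_set(empcpds))
        self.empcpd_sets[name] = rel
        return rel

    def load_empcpd_set(self, name):
        if name not in self.empcpd_sets:
            raise PipelineError(
                f"no empirical compound set {name!r}; available: {sorted(self.empcpd_sets)}"
            )
        return parse_empcpd_set((self.root_dir / self.empcpd_sets[name]).read_text())

    def default_name(self, stage):
        k = self._counters.get(stage, 0) + 1
        self._counters[stage] = k
        return f"{stage}_{k}"

    def log_command(self, command, params, inputs=(), outputs=()):
        self.command_log.append(
            {
                "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
                "command": command,
                "parameters": {k: _jsonable(v) for k, v in sorted(params.items())},
                "inputs": list(inputs),
                "outputs": list(outputs),
            }
        )

    # -- convenience --------------------------------------------------------

    def acquisition_names(self, sample_type=None):
        return [
            a.name
            for a in self.acquisitions
            if sample_type is None or a.sample_type == sample_type
        ]

    def batch_labels(self):
        return {a.name: a.batch for a in self.acquisitions}


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    return v


def assemble(metadata_csv, out_dir, overwrite: bool = False) -> Experiment:
    """Create an experiment directory from a sample metadata CSV."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise PipelineError(
                f"{out_dir} exists and is not empty; pass overwrite=True to replace"
            )
    out_dir.mkdir(parents=True, exist_ok=True)
    acquisitions = read_sample_metadata(metadata_csv)
    exp = Experiment(root_dir=out_dir, acquisitions=acquisitions)
    exp.log_command("assemble", {"metadata_csv": str(metadata_csv), "out_dir": str(out_dir)})
    exp.save()
    return exp


# ---------------------------------------------------------------------------
# Step registry
# ---------------------------------------------------------------------------

def _step_ingest_table(exp, params):
    from .io.feature_table import read_feature_table as _read

    table = _read(params["path"], dialect=params.get("dialect", "asari"))
    name = params.get("out") or exp.default_name("ingested")
    unknown = [a for a in table.acquisitions if a not in set(exp.acquisition_names())]
    if unknown:
        raise PipelineError(
            f"feature table columns not registered as acquisitions: {unknown}"
        )
    exp.save_table(table, name)
    return [name]


def _step_qc_metrics(exp, params):
    from .qaqc import acquisition_metrics

    table = exp.load_table(params["table"])
    metrics = acquisition_metrics(table)
    out = exp.root_dir / "qaqc" / f"{params['table']}_metrics.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    metrics.table.to_csv(out, index_label="acquisition")
    return [str(out.relative_to(exp.root_dir))]


def _step_detect_outliers(exp, params):
    from .qaqc import acquisition_metrics, detect_failed_acquisitions

    table = exp.load_table(params["table"])
    metrics = acquisition_metrics(table)
    flagged = detect_failed_acquisitions(
        metrics, z_threshold=float(params.get("z_threshold", -2.0))
    )
    out = exp.root_dir / "qaqc" / f"{params['table']}_flagged.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps([{"acquisition": a, "z": z} for a, z in flagged], indent=2))
    outputs = [str(out.relative_to(exp.root_dir))]
    if params.get("drop") and flagged:
        m = table.intensity_matrix()
        keep = [a for a in table.acquisitions if a not in {a for a, _ in flagged}]
        name = params.get("out") or exp.default_name("outliers_dropped")
        exp.save_table(table.with_matrix(m[keep], name), name)
        outputs.append(name)
    return outputs


def _table_to_table(stage, fn):
    def step(exp, params):
        table = exp.load_table(params["table"])
        result = fn(exp, table, params)
        name = params.get("out") or exp.default_name(stage)
        exp.save_table(result, name)
        return [name]

    return step


def _normalize_fn(exp, table, params):
    from .qaqc import tic_normalize

    out, _ = tic_normalize(table)
    return out


def _blank_mask_fn(exp, table, params):
    from .qaqc import blank_mask

    blanks = params.get("blanks") or [
        b for b in exp.acquisition_names("blank") if b in table.acquisitions
    ]
    out, _ = blank_mask(
        table,
        blanks,
        ratio_k=float(params.get("ratio_k", 3.0)),
        aggregator=params.get("aggregator", "mean"),
    )
    return out


def _drop_rare_fn(exp, table, params):
    from .qaqc import drop_rare_features

    return drop_rare_features(table, min_fraction=float(params.get("min_fraction", 0.25)))


def _impute_fn(exp, table, params):
    from .qaqc import impute_missing

    return impute_missing(table)


def _batch_correct_fn(exp, table, params):
    from .qaqc import combat_correct

    labels = {a: b for a, b in exp.batch_labels().items() if a in table.acquisitions}
    return combat_correct(table, labels)


def _step_build_empcpds(exp, params):
    from .preannotation import build_empirical_compounds

    table = exp.load_table(params["table"])
    empcpds, singletons = build_empirical_compounds(
        table,
        mz_tol_ppm=float(params.get("mz_tol_ppm", 5.0)),
        rt_tol_s=float(params.get("rt_tol_s", 2.0)),
        ion_mode=params.get("ion_mode", "pos"),
    )
    name = params.get("out") or exp.default_name("empcpds")
    exp.save_empcpd_set(empcpds, name)
    singles = exp.root_dir / "empcpds" / f"{name}_singletons.json"
    singles.write_text(json.dumps(singletons, indent=2))
    return [name]


def _step_annotate_l4(exp, params):
    from .annotation import annotate_level4
    from .io.reference import read_compound_list

    empcpds = exp.load_empcpd_set(params["empcpds"])
    compounds = read_compound_list(params["compounds"])
    annotate_level4(empcpds, compounds, mz_tol_ppm=float(params.get("mz_tol_ppm", 5.0)))
    name = params.get("out") or params["empcpds"]
    exp.save_empcpd_set(empcpds, name)
    return [name]


def _step_annotate_l1b(exp, params):
    from .annotation import annotate_level1b
    from .io.reference import read_standards

    empcpds = exp.load_empcpd_set(params["empcpds"])
    standards = read_standards(params["standards"])
    annotate_level1b(
        empcpds,
        standards,
        mz_tol_ppm=float(params.get("mz_tol_ppm", 5.0)),
        rt_tol_s=float(params.get("rt_tol_s", 5.0)),
    )
    name = params.get("out") or params["empcpds"]
    exp.save_empcpd_set(empcpds, name)
    return [name]


def _step_map_ms2(exp, params):
    from .annotation import map_ms2_to_empcpds
    from .io.mzml import extract_ms2_from_mzml

    empcpds = exp.load_empcpd_set(params["empcpds"])
    spectra = []
    for path in params["mzml"] if isinstance(params["mzml"], (list, tuple)) else [params["mzml"]]:
        got, _ = extract_ms2_from_mzml(path)
        spectra.extend(got)
    empcpds, unmatched = map_ms2_to_empcpds(
        spectra,
        empcpds,
        mz_tol_ppm=float(params.get("mz_tol_ppm", 10.0)),
        rt_tol_s=float(params.get("rt_tol_s", 30.0)),
    )
    name = params.get("out") or params["empcpds"]
    exp.save_empcpd_set(empcpds, name)
    return [name]


def _step_annotate_ms2(exp, params):
    from .annotation import annotate_level2_1a
    from .io.msp import read_msp_library

    empcpds = exp.load_empcpd_set(params["empcpds"])
    library = read_msp_library(
        params["library"],
        is_authentic_standard=bool(params.get("authentic", False)),
    )
    annotate_level2_1a(
        empcpds,
        library,
        frag_tol_da=float(params.get("frag_tol_da", 0.01)),
        min_score=float(params.get("min_score", 0.60)),
        min_matched=int(params.get("min_matched", 3)),
    )
    name = params.get("out") or params["empcpds"]
    exp.save_empcpd_set(empcpds, name)
    return [name]


def _step_export(exp, params):
    from .io.export import export_three_tables

    out_dir = params.get("out_dir") or (exp.root_dir / "export")
    export = export_three_tables(
        exp, params["table"], params.get("empcpds"), out_dir
    )
    return [
        str(Path(p)) for p in (
            export.feature_table_path,
            export.annotation_table_path,
            export.sample_table_path,
        )
    ]


def _step_report(exp, params):
    from .report import generate_report

    path = generate_report(exp, params.get("out"))
    return [str(path)]


STEPS = {
    "ingest-table": _step_ingest_table,
    "qc-metrics": _step_qc_metrics,
    "detect-outliers": _step_detect_outliers,
    "normalize": _table_to_table("normalized", _normalize_fn),
    "blank-mask": _table_to_table("blank_masked", _blank_mask_fn),
    "drop-rare": _table_to_table("rare_dropped", _drop_rare_fn),
    "impute": _table_to_table("imputed", _impute_fn),
    "batch-correct": _table_to_table("batch_corrected", _batch_correct_fn),
    "build-empcpds": _step_build_empcpds,
    "annotate-l4": _step_annotate_l4,
    "annotate-l1b": _step_annotate_l1b,
    "map-ms2": _step_map_ms2,
    "annotate-ms2": _step_annotate_ms2,
    "export": _step_export,
    "report": _step_report,
}


def run_step(experiment_dir, step, params=None):
    """Execute one named pipeline step against an experiment directory.

    Returns the (re-loaded) experiment.  Unknown steps and missing input
    names raise :class:`PipelineError` listing what is available.
    """
    params = dict(params or {})
    if step not in STEPS:
        raise PipelineError(f"unknown step {step!r}; available: {sorted(STEPS)}")
    exp = experiment_dir if isinstance(experiment_dir, Experiment) else Experiment.load(experiment_dir)
    inputs = [v for k, v in params.items() if k in ("table", "empcpds")]
    outputs = STEPS[step](exp, params)
    exp.log_command(step, params, inputs=inputs, outputs=outputs)
    exp.save()
    return exp
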