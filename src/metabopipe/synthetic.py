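"""Seed-deterministic synthetic data with known ground truth.

Generators emit the same external formats the pipeline consumes (TSV/CSV/MSP/
JSON/mzML) plus a :class:`GroundTruth` record sufficient to score recovery
exactly, so every module is testable without downloads.

Default noise magnitudes (1 ppm m/z, 0.5 s RT, 5 % intensity jitter) are
realistic for orbitrap-class data while keeping planted structure recoverable
at default tolerances; all are overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation.types import RefSpectrum
from .models import Acquisition, Feature, FeatureTable, MSSpectrum
from .preannotation import (
    C13_C12,
    default_relation_table,
    isotope_label,
)


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    compound_members: dict = field(default_factory=dict)
    # compound key -> list of (feature_id, isotope_tag, modification_tag)
    neutral_masses: dict = field(default_factory=dict)
    retention_times: dict = field(default_factory=dict)
    batch_location: dict = field(default_factory=dict)  # batch -> per-feature dict
    batch_scale: dict = field(default_factory=dict)     # batch -> scale factor
    failed_acquisitions: list = field(default_factory=list)
    blank_acquisitions: list = field(default_factory=list)
    spectrum_compounds: dict = field(default_factory=dict)  # query id -> compound name

    def to_json(self):
        return json.dumps(
            {
                "compound_members": {str(k): v for k, v in self.compound_members.items()},
                "neutral_masses": {str(k): v for k, v in self.neutral_masses.items()},
                "retention_times": {str(k): v for k, v in self.retention_times.items()},
                "batch_location": {
                    str(b): dict(v) for b, v in self.batch_location.items()
                },
                "batch_scale": {str(b): v for b, v in self.batch_scale.items()},
                "failed_acquisitions": list(self.failed_acquisitions),
                "blank_acquisitions": list(self.blank_acquisitions),
                "spectrum_compounds": dict(self.spectrum_compounds),
            },
            indent=2,
        )


def generate_feature_experiment(
    n_compounds: int = 12,
    n_samples: int = 10,
    n_batches: int = 1,
    ion_mode: str = "pos",
    seed: int = 0,
    mz_noise_ppm: float = 1.0,
    rt_noise_s: float = 0.5,
    n_blanks: int = 0,
    blank_carryover: float = 0.05,
    failed_fraction: float = 0.0,
    n_failed: int = 0,
    batch_shift: float = 1.0,
    batch_scale: float = 1.0,
):
    """Generate a feature table with planted empirical-compound structure.

    Per compound: neutral mass ~ U(80, 900) Da, RT ~ U(30, 1200) s; the anchor
    adduct M0 is always present plus a random subset of further adducts and
    isotopologues at exact relation deltas, perturbed by m/z noise (normal,
    sigma in ppm) and RT jitter.  Base intensities are log-normal; batch
    effects are applied on the log10 scale (location drawn per batch x
    feature around ``batch_shift`` for non-reference batches, spread scaled by
    ``batch_scale``); blanks carry ``blank_carryover`` of the mean study
    signal; failed injections have ``failed_fraction`` of features zeroed.

    Returns ``(FeatureTable, acquisitions, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    relations = default_relation_table(ion_mode)
    adducts = [r for r in relations if r.kind == "adduct" and r.charge == 1]
    anchor = next(a for a in adducts if a.anchor)
    others = [a for a in adducts if not a.anchor]

    sample_names = [f"S{i + 1:03d}" for i in range(n_samples)]
    blank_names = [f"B{i + 1:03d}" for i in range(n_blanks)]
    batches = [str(1 + i % n_batches) for i in range(n_samples)]

    truth = GroundTruth(blank_acquisitions=list(blank_names))
    features = []
    fid_counter = 0
    for c in range(n_compounds):
        mass = rng.uniform(80.0, 900.0)
        rt = rng.uniform(30.0, 1200.0)
        truth.neutral_masses[c] = mass
        truth.retention_times[c] = rt
        cells = [(0, anchor)]
        # guaranteed second member: the M+1 isotopologue of the anchor
        cells.append((1, anchor))
        for k in (2, 3):
            if rng.random() < 0.3:
                cells.append((k, anchor))
        for a in others:
            if rng.random() < 0.4:
                cells.append((0, a))
                if rng.random() < 0.3:
                    cells.append((1, a))
        base_log = rng.uniform(4.0, 7.0)  # log10 of the compound's base intensity
        members = []
        for k, adduct in cells:
            fid_counter += 1
            fid = f"F{fid_counter:05d}"
            theo_mz = mass + adduct.delta_mz + k * C13_C12
            mz = theo_mz * (1 + rng.normal(0.0, mz_noise_ppm) * 1e-6)
            frt = max(0.0, rt + rng.normal(0.0, rt_noise_s))
            # isotopologue/adduct relative abundance
            rel = (0.08 + 0.2 * rng.random()) ** k * (1.0 if adduct.anchor else rng.uniform(0.1, 0.8))
            sample_log = base_log + rng.normal(0.0, 0.3, size=n_samples)
            intensities = {}
            for s_i, s in enumerate(sample_names):
                intensities[s] = float(10 ** sample_log[s_i] * rel)
            members.append((fid, isotope_label(k), adduct.label))
            features.append(Feature(id=fid, mz=float(mz), rtime=float(frt), intensities=intensities))
        truth.compound_members[c] = members

    # batch effects on the log10 scale
    feature_ids = [f.id for f in features]
    if n_batches > 1:
        for b in sorted(set(batches)):
            if b == "1":
                truth.batch_location[b] = {fid: 0.0 for fid in feature_ids}
                truth.batch_scale[b] = 1.0
            else:
                locs = rng.normal(batch_shift, 0.3, size=len(feature_ids))
                truth.batch_location[b] = {
                    fid: float(v) for fid, v in zip(feature_ids, locs)
                }
                truth.batch_scale[b] = float(batch_scale)
        for f in features:
            vals = np.array([f.intensities[s] for s in sample_names])
            logs = np.log10(vals + 1.0)
            center = logs.mean()
            for s_i, s in enumerate(sample_names):
                b = batches[s_i]
                shifted = (
                    center
                    + (logs[s_i] - center) * truth.batch_scale.get(b, 1.0)
                    + truth.batch_location.get(b, {}).get(f.id, 0.0)
                )
                f.intensities[s] = float(max(0.0, 10**shifted - 1.0))

    # blanks: small carryover of the mean study signal
    for f in features:
        mean_study = float(np.mean([f.intensities[s] for s in sample_names]))
        for b in blank_names:
            f.intensities[b] = mean_study * blank_carryover * rng.uniform(0.2, 1.0)

    # failed injections: zero out a fraction of one or more study samples
    failed = []
    if n_failed > 0 and failed_fraction > 0:
        chosen = rng.choice(n_samples, size=n_failed, replace=False)
        for s_i in sorted(chosen):
            s = sample_names[s_i]
            failed.append(s)
            kill = rng.random(len(features)) < failed_fraction
            for f, k in zip(features, kill):
                if k:
                    f.intensities[s] = 0.0
    truth.failed_acquisitions = failed

    acquisitions = [
        Acquisition(name=s, filepath=f"{s}.mzML", sample_type="study", batch=batches[i])
        for i, s in enumerate(sample_names)
    ] + [
        Acquisition(name=b, filepath=f"{b}.mzML", sample_type="blank", batch="1")
        for b in blank_names
    ]
    table = FeatureTable(
        features=features,
        acquisitions=sample_names + blank_names,
        provenance_tag="synthetic",
    )
    return table, acquisitions, truth


def generate_spectral_library(
    n_compounds: int = 20,
    peaks_per_spectrum: int = 8,
    seed: int = 0,
    intensity_jitter: float = 0.05,
    n_dropped_peaks: int = 1,
    precursor_jitter_ppm: float = 2.0,
    authentic: bool = False,
):
    """Generate reference spectra plus jittered query copies.

    Returns ``(refs, queries, GroundTruth)``: queries are copies of the
    references with multiplicative intensity jitter, ``n_dropped_peaks``
    random peaks removed and the precursor perturbed within the given ppm.
    """
    if peaks_per_spectrum < 3:
        raise ValueError("peaks_per_spectrum must be >= 3")
    rng = np.random.default_rng(seed)
    refs, queries = [], []
    truth = GroundTruth()
    for c in range(n_compounds):
        name = f"compound_{c + 1:03d}"
        precursor = rng.uniform(150.0, 800.0)
        frag_mz = np.sort(rng.uniform(50.0, precursor - 1.0, size=peaks_per_spectrum))
        frag_int = rng.uniform(0.05, 1.0, size=peaks_per_spectrum)
        refs.append(
            RefSpectrum(
                compound_name=name,
                precursor_mz=float(precursor),
                peaks=list(zip(frag_mz.tolist(), frag_int.tolist())),
                source_library="synthetic_library",
                is_authentic_standard=authentic,
            )
        )
        q_int = frag_int * (1 + rng.normal(0.0, intensity_jitter, size=peaks_per_spectrum))
        q_int = np.clip(q_int, 1e-6, None)
        keep = np.ones(peaks_per_spectrum, dtype=bool)
        if n_dropped_peaks > 0:
            drop = rng.choice(peaks_per_spectrum, size=n_dropped_peaks, replace=False)
            keep[drop] = False
        q_precursor = precursor * (
            1 + rng.uniform(-precursor_jitter_ppm, precursor_jitter_ppm) * 1e-6
        )
        qid = f"query_{c + 1:03d}"
        queries.append(
            MSSpectrum(
                peaks=list(zip(frag_mz[keep].tolist(), q_int[keep].tolist())),
                ms_level=2,
                precursor_mz=float(q_precursor),
                retention_time=float(rng.uniform(30.0, 1200.0)),
                source_acquisition=qid,
            )
        )
        truth.spectrum_compounds[qid] = name
    return refs, queries, truth


def generate_batch_matrix(
    n_features: int = 50,
    n_samples: int = 20,
    shift: float = 1.0,
    shift_spread: float = 0.5,
    scale: float = 1.5,
    seed: int = 0,
):
    """Two-batch simulation with known location/scale effects on the log scale.

    Batch 1 features ~ N(mu_f, sigma_f) per feature (log10 intensities); batch
    2 adds a per-feature location effect drawn as N(shift, shift_spread) and
    multiplies the spread by ``scale``.  A nonzero spread keeps the
    planted-vs-estimated correlation well defined.  Returns ``(FeatureTable, batch_labels,
    planted_location: dict feature -> effect)``.
    """
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    sample_names = [f"S{i + 1:03d}" for i in range(n_samples)]
    batch_labels = {s: ("1" if i < half else "2") for i, s in enumerate(sample_names)}
    mu = rng.uniform(4.0, 6.5, size=n_features)
    sigma = rng.uniform(0.1, 0.3, size=n_features)
    planted = rng.normal(shift, shift_spread, size=n_features)
    features = []
    planted_map = {}
    for f_i in range(n_features):
        fid = f"F{f_i + 1:05d}"
        logs = rng.normal(mu[f_i], sigma[f_i], size=n_samples)
        for s_i in range(half, n_samples):
            logs[s_i] = mu[f_i] + (logs[s_i] - mu[f_i]) * scale + planted[f_i]
        intensities = {
            s: float(max(0.0, 10 ** logs[s_i] - 1.0))
            for s_i, s in enumerate(sample_names)
        }
        mz = rng.uniform(80.0, 900.0)
        features.append(
            Feature(id=fid, mz=float(mz), rtime=float(rng.uniform(30, 1200)), intensities=intensities)
        )
        planted_map[fid] = float(planted[f_i])
    table = FeatureTable(
        features=features, acquisitions=sample_names, provenance_tag="batch_sim"
    )
    return table, batch_labels, planted_map


def materialize_experiment(
    out_dir,
    seed: int = 0,
    n_compounds: int = 12,
    n_samples: int = 8,
    n_batches: int = 2,
    n_blanks: int = 2,
    ion_mode: str = "pos",
    n_decoy_compounds: int = 10,
):
    """Write a complete synthetic experiment input set to ``out_dir``.

    Emits features.tsv, metadata.csv, compounds.csv, standards.csv,
    library.msp, ms2.mzML and ground_truth.json — everything needed to drive
    the full pipeline end to end.  Returns ``(paths dict, GroundTruth)``.
    """
    from pathlib import Path

    from .io.feature_table import write_feature_table
    from .io.metadata import write_sample_metadata
    from .io.msp import write_msp_library
    from .io.mzml import write_mzml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed + 1_000_003)

    table, acquisitions, truth = generate_feature_experiment(
        n_compounds=n_compounds,
        n_samples=n_samples,
        n_batches=n_batches,
        ion_mode=ion_mode,
        seed=seed,
        n_blanks=n_blanks,
    )
    paths = {
        "features": out_dir / "features.tsv",
        "metadata": out_dir / "metadata.csv",
        "compounds": out_dir / "compounds.csv",
        "standards": out_dir / "standards.csv",
        "library": out_dir / "library.msp",
        "ms2": out_dir / "ms2.mzML",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_feature_table(table, paths["features"])
    write_sample_metadata(acquisitions, paths["metadata"])

    relations = default_relation_table(ion_mode)
    anchor = next(r for r in relations if r.kind == "adduct" and r.anchor)

    # compound list: planted masses plus random decoys
    with open(paths["compounds"], "w") as fh:
        fh.write("name,formula,neutral_mono_mass\n")
        for c, mass in sorted(truth.neutral_masses.items()):
            fh.write(f"cpd_{c:03d},,{mass!r}\n")
        for d in range(n_decoy_compounds):
            fh.write(f"decoy_{d:03d},,{rng.uniform(80.0, 900.0)!r}\n")

    # authentic standards: anchor-adduct m/z and RT of every other compound
    with open(paths["standards"], "w") as fh:
        fh.write("name,mz,rtime\n")
        for c in sorted(truth.neutral_masses)[::2]:
            mz = (truth.neutral_masses[c] + anchor.delta_mz) / anchor.charge
            fh.write(f"cpd_{c:03d},{mz!r},{truth.retention_times[c]!r}\n")

    # reference MS2 spectra per compound + jittered experimental queries
    refs, queries = [], []
    for c in sorted(truth.neutral_masses):
        precursor = (truth.neutral_masses[c] + anchor.delta_mz) / anchor.charge
        n_peaks = 8
        frag_mz = np.sort(rng.uniform(50.0, max(60.0, precursor - 1.0), n_peaks))
        frag_int = rng.uniform(0.05, 1.0, n_peaks)
        refs.append(
            RefSpectrum(
                compound_name=f"cpd_{c:03d}",
                precursor_mz=float(precursor),
                peaks=list(zip(frag_mz.tolist(), frag_int.tolist())),
                source_library="synthetic_library",
            )
        )
        q_int = np.clip(frag_int * (1 + rng.normal(0, 0.05, n_peaks)), 1e-6, None)
        keep = np.ones(n_peaks, dtype=bool)
        keep[rng.integers(0, n_peaks)] = False
        qid = f"q_{c:03d}"
        queries.append(
            MSSpectrum(
                peaks=list(zip(frag_mz[keep].tolist(), q_int[keep].tolist())),
                ms_level=2,
                precursor_mz=float(precursor * (1 + rng.normal(0, 1.0) * 1e-6)),
                retention_time=float(truth.retention_times[c] + rng.normal(0, 3.0)),
                source_acquisition=qid,
            )
        )
        truth.spectrum_compounds[qid] = f"cpd_{c:03d}"
    write_msp_library(refs, paths["library"])
    write_mzml(queries, paths["ms2"])
    paths["ground_truth"].write_text(truth.to_json())
    return paths, truth
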