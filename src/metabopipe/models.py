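"""Core data models for LC-MS metabolomics processing.

The central object is the :class:`EmpiricalCompound` — a group of degenerate
features (isotopologues and adducts of one tentative metabolite) carrying a
chained, ordered list of :class:`Annotation` records.  All models serialize
losslessly to JSON with a deterministic key order so that downstream tools can
be chained on the serialized form.

Units: m/z and masses in Da, retention times in seconds, intensities in
arbitrary counts.  ppm error is defined as ``1e6 * delta_m / m_reference``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

#: Confidence levels in decreasing order of confidence.  1a = MS2 match to an
#: authentic-standard library; 1b = m/z + RT match to authentic standards;
#: 2 = MS2 match to an external library; 4 = neutral-mass-only match.
ANNOTATION_LEVELS = ("1a", "1b", "2", "4")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(ANNOTATION_LEVELS)}


# ---------------------------------------------------------------------------
# Spectra and peaks
# ---------------------------------------------------------------------------

@dataclass
class MSSpectrum:
    """A centroided mass spectrum: sorted (mz, intensity) peak list."""

    peaks: list  # list of (mz, intensity) tuples, sorted ascending by mz
    ms_level: int = 1
    precursor_mz: Optional[float] = None
    retention_time: Optional[float] = None  # seconds
    source_acquisition: Optional[str] = None

    def __post_init__(self):
        self.peaks = [(float(m), float(i)) for m, i in self.peaks]
        self.peaks.sort(key=lambda p: p[0])
        self.validate()

    def validate(self):
        errs = []
        if self.ms_level < 1:
            errs.append("ms_level must be >= 1")
        if any(i < 0 for _, i in self.peaks):
            errs.append("all intensities must be >= 0")
        if self.ms_level >= 2 and self.precursor_mz is None:
            errs.append("precursor_mz required when ms_level >= 2")
        if self.ms_level < 2 and self.precursor_mz is not None:
            errs.append("precursor_mz only allowed when ms_level >= 2")
        if errs:
            raise ValidationError("invalid MSSpectrum", errs)

    @property
    def mz_values(self):
        return [p[0] for p in self.peaks]

    @property
    def intensities(self):
        return [p[1] for p in self.peaks]

    def to_dict(self):
        return {
            "ms_level": self.ms_level,
            "precursor_mz": self.precursor_mz,
            "retention_time": self.retention_time,
            "source_acquisition": self.source_acquisition,
            "peaks": [[m, i] for m, i in self.peaks],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            peaks=[tuple(p) for p in d["peaks"]],
            ms_level=d.get("ms_level", 1),
            precursor_mz=d.get("precursor_mz"),
            retention_time=d.get("retention_time"),
            source_acquisition=d.get("source_acquisition"),
        )


@dataclass
class ElutionPeak:
    """An intensity peak along the chromatographic axis, within one sample."""

    mz: float
    rt_apex: float
    rt_left: float
    rt_right: float
    area: float
    height: float
    snr: Optional[float] = None

    def __post_init__(self):
        errs = []
        if not (self.rt_left <= self.rt_apex <= self.rt_right):
            errs.append("rt_left <= rt_apex <= rt_right required")
        if self.area <= 0 or self.height <= 0:
            errs.append("area and height must be > 0")
        if errs:
            raise ValidationError("invalid ElutionPeak", errs)


@dataclass
class Feature:
    """An aligned cross-sample signal with m/z, RT and per-sample intensities."""

    id: str
    mz: float
    rtime: float
    intensities: dict = field(default_factory=dict)  # acquisition id -> counts
    snr: Optional[float] = None
    goodness_fit: Optional[float] = None

    def __post_init__(self):
        errs = []
        if self.mz <= 0:
            errs.append(f"feature {self.id}: mz must be > 0")
        if self.rtime < 0:
            errs.append(f"feature {self.id}: rtime must be >= 0")
        if any(v < 0 for v in self.intensities.values()):
            errs.append(f"feature {self.id}: intensities must be >= 0")
        if errs:
            raise ValidationError("invalid Feature", errs)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """One annotation of an empirical compound at a given confidence level.

    Level-specific evidence requirements (enforced by :meth:`validate`):

    * ``1b`` — retention-time evidence (``rt_error_s`` in ``evidence``)
    * ``1a`` / ``2`` — an MS2 similarity ``score``
    * ``4`` — a mass/formula match record (``ppm_error`` in ``evidence`` or a
      ``formula`` identifier)
    """

    level: str
    compound_name: str
    identifiers: dict = field(default_factory=dict)
    score: Optional[float] = None
    source: str = ""
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        errs = []
        if self.level not in ANNOTATION_LEVELS:
            errs.append(f"unknown level {self.level!r}")
        else:
            if self.level == "1b" and "rt_error_s" not in self.evidence:
                errs.append("level 1b requires rt evidence (evidence['rt_error_s'])")
            if self.level in ("1a", "2") and self.score is None:
                errs.append(f"level {self.level} requires an MS2 score")
            if self.level == "4" and (
                "ppm_error" not in self.evidence and "formula" not in self.identifiers
            ):
                errs.append("level 4 requires a mass/formula match record")
        if errs:
            raise ValidationError("invalid Annotation", errs)

    def sort_key(self):
        # level rank, then descending score (None sorts last), then ascending
        # combined match error when recorded (e.g. level 1b), then source
        score = self.score if self.score is not None else -math.inf
        combined = self.evidence.get("combined_error", math.inf)
        return (
            _LEVEL_RANK.get(self.level, 99),
            -score,
            combined,
            self.source,
            self.compound_name,
        )

    def to_dict(self):
        return {
            "level": self.level,
            "compound_name": self.compound_name,
            "identifiers": dict(sorted(self.identifiers.items())),
            "score": self.score,
            "source": self.source,
            "evidence": dict(sorted(self.evidence.items())),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            level=d["level"],
            compound_name=d["compound_name"],
            identifiers=dict(d.get("identifiers") or {}),
            score=d.get("score"),
            source=d.get("source", ""),
            evidence=dict(d.get("evidence") or {}),
        )


# ---------------------------------------------------------------------------
# Empirical compound
# ---------------------------------------------------------------------------

@dataclass
class MS1Member:
    """One MS1 feature inside an empirical compound, with its grid tags."""

    feature_id: str
    isotope: str        # e.g. "M0", "13C/12C", "13C/12C*2"
    modification: str   # e.g. "M+H[1+]", "M+Na[1+]"
    mz: Optional[float] = None
    rtime: Optional[float] = None
    charge: int = 1

    def to_dict(self):
        return {
            "feature_id": self.feature_id,
            "isotope": self.isotope,
            "modification": self.modification,
            "mz": self.mz,
            "rtime": self.rtime,
            "charge": self.charge,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            feature_id=d["feature_id"],
            isotope=d["isotope"],
            modification=d["modification"],
            mz=d.get("mz"),
            rtime=d.get("rtime"),
            charge=d.get("charge", 1),
        )


@dataclass
class EmpiricalCompound:
    """A grid of degenerate features attributed to one tentative metabolite."""

    interim_id: str
    neutral_formula_mass: Optional[float] = None
    neutral_formula: Optional[str] = None
    charge_sign: int = 1
    ms1_features: list = field(default_factory=list)   # list[MS1Member]
    ms2_spectra: list = field(default_factory=list)    # list[MSSpectrum]
    annotations: list = field(default_factory=list)    # list[Annotation]

    def validate(self):
        errs = []
        if self.charge_sign not in (1, -1):
            errs.append(f"{self.interim_id}: charge_sign must be +1 or -1")
        seen = set()
        for m in self.ms1_features:
            key = (m.isotope, m.modification)
            if key in seen:
                errs.append(
                    f"{self.interim_id}: duplicate (isotope, modification) pair {key}"
                )
            seen.add(key)
        for a in self.annotations:
            try:
                a.validate()
            except ValidationError as e:
                errs.extend(f"{self.interim_id}: {v}" for v in e.violations)
        ranks = [a.sort_key() for a in self.annotations]
        if ranks != sorted(ranks):
            errs.append(f"{self.interim_id}: annotations not ordered by confidence")
        if errs:
            raise ValidationError(f"invalid EmpiricalCompound {self.interim_id}", errs)

    def add_annotation(self, annotation: Annotation) -> bool:
        """Attach an annotation, suppressing duplicates by (source, name, level).

        Returns True if the annotation was added, False if it was a duplicate.
        Keeps the annotation list ordered by descending confidence.
        """
        key = (annotation.source, annotation.compound_name, annotation.level)
        for existing in self.annotations:
            if (existing.source, existing.compound_name, existing.level) == key:
                return False
        self.annotations.append(annotation)
        self.annotations.sort(key=lambda a: a.sort_key())
        return True

    @property
    def feature_ids(self):
        return [m.feature_id for m in self.ms1_features]

    def to_dict(self):
        return {
            "interim_id": self.interim_id,
            "neutral_formula": self.neutral_formula,
            "neutral_formula_mass": self.neutral_formula_mass,
            "charge_sign": self.charge_sign,
            "MS1_pseudo_Spectra": [m.to_dict() for m in self.ms1_features],
            "MS2_Spectra": [s.to_dict() for s in self.ms2_spectra],
            "annotations": [a.to_dict() for a in self.annotations],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            interim_id=d["interim_id"],
            neutral_formula_mass=d.get("neutral_formula_mass"),
            neutral_formula=d.get("neutral_formula"),
            charge_sign=d.get("charge_sign", 1),
            ms1_features=[MS1Member.from_dict(m) for m in d.get("MS1_pseudo_Spectra", [])],
            ms2_spectra=[MSSpectrum.from_dict(s) for s in d.get("MS2_Spectra", [])],
            annotations=[Annotation.from_dict(a) for a in d.get("annotations", [])],
        )


def serialize_empcpd_set(empcpds) -> str:
    """Serialize a list of empirical compounds to deterministic JSON text.

    Key order is fixed by construction, so equal inputs yield byte-identical
    output.  Every compound is validated first; a violation raises
    :class:`ValidationError` naming the offending ``interim_id``.
    """
    for ec in empcpds:
        ec.validate()
    return json.dumps([ec.to_dict() for ec in empcpds], indent=2, allow_nan=False)


def parse_empcpd_set(text: str):
    """Parse JSON text produced by :func:`serialize_empcpd_set`.

    Raises :class:`~metabopipe.errors.FormatError` on malformed JSON (with
    position) and :class:`ValidationError` if a parsed object violates the
    type invariants.
    """
    from .errors import FormatError

    try:
        raw = json.loads(text)
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed JSON at line {e.lineno} column {e.colno}: {e.msg}")
    if not isinstance(raw, list):
        raise FormatError("empirical compound set must be a JSON array")
    out = []
    for entry in raw:
        try:
            ec = EmpiricalCompound.from_dict(entry)
        except (KeyError, TypeError) as e:
            raise FormatError(f"empirical compound entry missing field: {e}")
        ec.validate()
        out.append(ec)
    return out


# ---------------------------------------------------------------------------
# Feature table and acquisitions
# ---------------------------------------------------------------------------

@dataclass
class Acquisition:
    """One data file produced by analyzing a sample."""

    name: str
    filepath: str = ""
    sample_type: str = "study"  # study | blank | pool | standard
    batch: str = "1"
    metadata: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "name": self.name,
            "filepath": self.filepath,
            "sample_type": self.sample_type,
            "batch": self.batch,
            "metadata": dict(sorted(self.metadata.items())),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            name=d["name"],
            filepath=d.get("filepath", ""),
            sample_type=d.get("sample_type", "study"),
            batch=str(d.get("batch", "1")),
            metadata=dict(d.get("metadata") or {}),
        )


@dataclass
class FeatureTable:
    """A matrix of features x acquisitions plus per-feature metadata."""

    features: list = field(default_factory=list)       # list[Feature]
    acquisitions: list = field(default_factory=list)   # ordered acquisition ids
    provenance_tag: str = "raw"

    def validate(self):
        """Return a list of violation records; empty iff all invariants hold."""
        violations = []
        seen = set()
        for f in self.features:
            if f.id in seen:
                violations.append(f"duplicate id: feature {f.id!r} appears more than once")
            seen.add(f.id)
        declared = set(self.acquisitions)
        for f in self.features:
            for acq in f.intensities:
                if acq not in declared:
                    violations.append(
                        f"feature {f.id!r} references undeclared acquisition {acq!r}"
                    )
        return violations

    def feature_ids(self):
        return [f.id for f in self.features]

    def get_feature(self, feature_id):
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)

    def intensity_matrix(self):
        """Return intensities as a pandas DataFrame (features x acquisitions).

        Missing cells are zeros by convention; imputation is an explicit step.
        """
        import numpy as np
        import pandas as pd

        data = np.zeros((len(self.features), len(self.acquisitions)))
        col_idx = {a: j for j, a in enumerate(self.acquisitions)}
        for i, f in enumerate(self.features):
            for acq, v in f.intensities.items():
                data[i, col_idx[acq]] = v
        return pd.DataFrame(
            data, index=[f.id for f in self.features], columns=list(self.acquisitions)
        )

    def with_matrix(self, matrix, provenance_tag):
        """Build a new table from a (possibly column/row-subset) matrix.

        Feature metadata (mz, rtime, quality) is carried over by id; the input
        table is left untouched.
        """
        by_id = {f.id: f for f in self.features}
        feats = []
        for fid in matrix.index:
            src = by_id[fid]
            feats.append(
                Feature(
                    id=src.id,
                    mz=src.mz,
                    rtime=src.rtime,
                    intensities={a: float(matrix.at[fid, a]) for a in matrix.columns},
                    snr=src.snr,
                    goodness_fit=src.goodness_fit,
                )
            )
        return FeatureTable(
            features=feats,
            acquisitions=list(matrix.columns),
            provenance_tag=provenance_tag,
        )


def validate_feature_table(table: FeatureTable):
    """Report invariant violations of a feature table (empty list == valid)."""
    return table.validate()


# ---------------------------------------------------------------------------
# Metabolic model carrier types (data only; no flux computation)
# ---------------------------------------------------------------------------

@dataclass
class Compound:
    id: str
    name: str = ""
    formula: str = ""
    neutral_mono_mass: Optional[float] = None


@dataclass
class Reaction:
    id: str
    substrates: list = field(default_factory=list)  # compound ids
    products: list = field(default_factory=list)    # compound ids
    enzymes: list = field(default_factory=list)     # enzyme ids


@dataclass
class Enzyme:
    id: str
    genes: list = field(default_factory=list)


@dataclass
class Gene:
    id: str
    name: str = ""


@dataclass
class Pathway:
    id: str
    name: str = ""
    reactions: list = field(default_factory=list)  # reaction ids


@dataclass
class MetabolicNetwork:
    """A collection of reactions and their associated metabolites."""

    compounds: dict = field(default_factory=dict)  # id -> Compound
    reactions: dict = field(default_factory=dict)  # id -> Reaction
    enzymes: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    pathways: dict = field(default_factory=dict)

    def validate(self):
        errs = []
        for rxn in self.reactions.values():
            for cid in list(rxn.substrates) + list(rxn.products):
                if cid not in self.compounds:
                    errs.append(f"reaction {rxn.id}: unknown compound {cid}")
        for pw in self.pathways.values():
            for rid in pw.reactions:
                if rid not in self.reactions:
                    errs.append(f"pathway {pw.id}: unknown reaction {rid}")
        if errs:
            raise ValidationError("invalid metabolic network", errs)
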