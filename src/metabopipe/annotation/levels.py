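"""Annotators that attach leveled annotations to empirical compounds.

All annotators mutate the passed empirical compounds in place (adding
Annotation records) and also return them, so calls can be chained.  Duplicate
annotations — same (source, compound name, level) — are suppressed, making
every annotator idempotent.
"""

from __future__ import annotations

import warnings

from ..models import Annotation
from .index import build_precursor_index
from .similarity import cosine_score


def _ppm(observed, reference):
    return (observed - reference) / reference * 1e6


def annotate_level4(empcpds, compound_list, mz_tol_ppm: float = 5.0):
    """Attach level-4 (neutral-mass-only) annotations.

    ``compound_list`` entries need ``name`` (or ``compound_name`` / ``id``),
    ``neutral_mono_mass`` and optionally ``formula``.  All compounds within
    the ppm window attach — isomers are not resolved at level 4.
    """
    if not compound_list:
        warnings.warn("empty compound list; level-4 annotation is a no-op")
        return empcpds
    for ec in empcpds:
        if ec.neutral_formula_mass is None:
            continue
        hits = []
        for cpd in compound_list:
            mass = getattr(cpd, "neutral_mono_mass", None)
            if mass is None and isinstance(cpd, dict):
                mass = cpd.get("neutral_mono_mass")
            if mass is None or mass <= 0:
                continue
            ppm_err = _ppm(ec.neutral_formula_mass, mass)
            if abs(ppm_err) <= mz_tol_ppm:
                hits.append((abs(ppm_err), ppm_err, cpd))
        for _, ppm_err, cpd in sorted(hits, key=lambda h: (h[0], _cpd_name(h[2]))):
            ec.add_annotation(
                Annotation(
                    level="4",
                    compound_name=_cpd_name(cpd),
                    identifiers=_cpd_identifiers(cpd),
                    score=None,
                    source=_cpd_source(cpd),
                    evidence={"ppm_error": ppm_err},
                )
            )
    return empcpds


def _cpd_name(cpd):
    if isinstance(cpd, dict):
        return cpd.get("name") or cpd.get("compound_name") or cpd.get("id", "")
    return getattr(cpd, "name", "") or getattr(cpd, "compound_name", "") or getattr(cpd, "id", "")


def _cpd_identifiers(cpd):
    ids = {}
    if isinstance(cpd, dict):
        if cpd.get("formula"):
            ids["formula"] = cpd["formula"]
        if cpd.get("id"):
            ids["id"] = cpd["id"]
    else:
        if getattr(cpd, "formula", ""):
            ids["formula"] = cpd.formula
        if getattr(cpd, "id", ""):
            ids["id"] = cpd.id
    return ids


def _cpd_source(cpd):
    if isinstance(cpd, dict):
        return cpd.get("source", "compound_list")
    return getattr(cpd, "source", "compound_list")


def annotate_level1b(
    empcpds,
    standards,
    mz_tol_ppm: float = 5.0,
    rt_tol_s: float = 5.0,
):
    """Attach level-1b annotations by m/z + RT match to authentic standards.

    A member feature matches a standard iff |ppm(mz)| <= mz_tol_ppm (ppm
    against the standard's m/z, closed window) and |delta rt| <= rt_tol_s.
    Multiple in-window standards all attach, ordered by combined normalized
    error (ppm/tol)^2 + (rt/tol)^2.
    """
    for ec in empcpds:
        hits = []
        for member in ec.ms1_features:
            if member.mz is None or member.rtime is None:
                continue
            for std in standards:
                ppm_err = _ppm(member.mz, std.mz)
                rt_err = member.rtime - std.rtime
                if abs(ppm_err) <= mz_tol_ppm and abs(rt_err) <= rt_tol_s:
                    combined = (ppm_err / mz_tol_ppm) ** 2 + (
                        (rt_err / rt_tol_s) ** 2 if rt_tol_s > 0 else 0.0
                    )
                    hits.append((combined, std.compound_name, member, std, ppm_err, rt_err))
        for combined, _, member, std, ppm_err, rt_err in sorted(hits, key=lambda h: (h[0], h[1])):
            ec.add_annotation(
                Annotation(
                    level="1b",
                    compound_name=std.compound_name,
                    identifiers=dict(std.identifiers),
                    score=None,
                    source="authentic_standards",
                    evidence={
                        "ppm_error": ppm_err,
                        "rt_error_s": rt_err,
                        "combined_error": combined,
                        "matched_feature": member.feature_id,
                    },
                )
            )
    return empcpds


def map_ms2_to_empcpds(
    spectra,
    empcpds,
    mz_tol_ppm: float = 10.0,
    rt_tol_s: float = 30.0,
):
    """Attach experimental MS2 spectra to empirical compounds.

    A spectrum maps to an empirical compound when some member feature lies
    within both tolerances of the spectrum's precursor (ppm against the
    feature m/z).  With several candidates, the smallest combined normalized
    distance (ppm/tol)^2 + (rt/tol)^2 wins; ties break on interim_id.
    Returns ``(empcpds, unmatched_spectra)``.
    """
    unmatched = []
    for spectrum in spectra:
        best = None
        for ec in empcpds:
            for member in ec.ms1_features:
                if member.mz is None:
                    continue
                ppm_err = _ppm(spectrum.precursor_mz, member.mz)
                rt_err = (
                    (spectrum.retention_time or 0.0) - (member.rtime or 0.0)
                )
                if abs(ppm_err) <= mz_tol_ppm and abs(rt_err) <= rt_tol_s:
                    dist = (ppm_err / mz_tol_ppm) ** 2 + (
                        (rt_err / rt_tol_s) ** 2 if rt_tol_s > 0 else 0.0
                    )
                    key = (dist, ec.interim_id)
                    if best is None or key < best[0]:
                        best = (key, ec)
        if best is None:
            unmatched.append(spectrum)
        else:
            best[1].ms2_spectra.append(spectrum)
    return empcpds, unmatched


def annotate_level2_1a(
    empcpds,
    library,
    frag_tol_da: float = 0.01,
    min_score: float = 0.60,
    min_matched: int = 3,
    precursor_tol_ppm: float = 10.0,
):
    """Attach MS2-similarity annotations: level 1a (authentic) or 2 (external).

    For every attached experimental spectrum, candidate references come from
    the precursor interval-tree index; each candidate is scored with
    :func:`cosine_score`.  Matches passing both thresholds attach; when the
    same reference matches several spectra of one empirical compound, only
    the best score is kept.
    """
    if not library:
        warnings.warn("empty spectral library; MS2 annotation is a no-op")
        return empcpds
    index = build_precursor_index(library, mz_tol_ppm=precursor_tol_ppm)
    for ec in empcpds:
        best_by_ref = {}
        for spectrum in ec.ms2_spectra:
            if not spectrum.peaks:
                continue
            for ref in index.query(spectrum.precursor_mz):
                if not ref.peaks:
                    continue
                score, n_matched = cosine_score(spectrum, ref, frag_tol_da=frag_tol_da)
                if score < min_score or n_matched < min_matched:
                    continue
                key = (ref.source_library, ref.compound_name)
                prev = best_by_ref.get(key)
                if prev is None or score > prev[0]:
                    best_by_ref[key] = (score, n_matched, ref, spectrum)
        for (src, name), (score, n_matched, ref, spectrum) in sorted(best_by_ref.items()):
            level = "1a" if ref.is_authentic_standard else "2"
            identifiers = dict(ref.identifiers)
            if ref.formula:
                identifiers.setdefault("formula", ref.formula)
            ec.add_annotation(
                Annotation(
                    level=level,
                    compound_name=name,
                    identifiers=identifiers,
                    score=score,
                    source=src or "spectral_library",
                    evidence={
                        "n_matched_peaks": n_matched,
                        "precursor_ppm_error": _ppm(
                            spectrum.precursor_mz, ref.precursor_mz
                        ),
                    },
                )
            )
    return empcpds
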