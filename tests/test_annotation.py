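import numpy as np
import pytest

from metabopipe.annotation import (
    annotate_level1b,
    annotate_level2_1a,
    annotate_level4,
    build_precursor_index,
    cosine_score,
    map_ms2_to_empcpds,
)
from metabopipe.annotation.types import RefSpectrum, SpectralMatch, StandardEntry
from metabopipe.errors import MetaboPipeError, ValidationError
from metabopipe.models import Compound, EmpiricalCompound, MS1Member, MSSpectrum
from metabopipe.synthetic import generate_spectral_library

from oracles import linear_scan_query, optimal_pairing_score

# glucose/fructose formula mass (C6H12O6) from standard atomic masses
C6H12O6 = 6 * 12.0 + 12 * 1.0078250319 + 6 * 15.9949146221


def _random_refs(rng, n):
    refs = []
    for i in range(n):
        m = int(rng.integers(3, 9))
        mzs = np.sort(rng.uniform(50, 900, m))
        refs.append(
            RefSpectrum(
                compound_name=f"r{i:04d}",
                precursor_mz=float(rng.uniform(100, 900)),
                peaks=list(zip(mzs.tolist(), rng.uniform(1, 100, m).tolist())),
            )
        )
    return refs


class TestPrecursorIndex:
    def test_matches_linear_scan_1000x1000(self):
        rng = np.random.default_rng(42)
        refs = _random_refs(rng, 1000)
        index = build_precursor_index(refs, mz_tol_ppm=10.0)
        queries = rng.uniform(100, 900, 1000)
        # add exact hits so the equivalence is not vacuous
        queries[:50] = [r.precursor_mz for r in refs[:50]]
        n_hits = 0
        for q in queries:
            got = sorted(r.compound_name for r in index.query(q))
            want = sorted(r.compound_name for r in linear_scan_query(refs, q, 10.0))
            assert got == want
            n_hits += len(got)
        assert n_hits >= 50

    def test_empty_library(self):
        index = build_precursor_index([], mz_tol_ppm=10.0)
        assert index.query(500.0) == []

    def test_boundary_is_closed(self):
        ref = RefSpectrum("x", precursor_mz=500.0, peaks=[(100.0, 1.0)])
        index = build_precursor_index([ref], mz_tol_ppm=10.0)
        assert index.query(500.0 * (1 + 10e-6)) == [ref]
        assert index.query(500.0 * (1 - 10e-6)) == [ref]
        assert index.query(500.0 * (1 + 10.5e-6)) == []

    def test_missing_precursor_counted(self):
        refs = [
            RefSpectrum("a", precursor_mz=None, peaks=[(100.0, 1.0)]),
            RefSpectrum("b", precursor_mz=200.0, peaks=[(100.0, 1.0)]),
        ]
        index = build_precursor_index(refs, 10.0)
        assert index.n_indexed == 1 and index.n_skipped == 1


class TestCosineScore:
    def test_self_similarity(self):
        peaks = [(100.0, 5.0), (150.0, 2.0), (200.0, 9.0)]
        score, n = cosine_score(peaks, peaks, 0.01)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_disjoint_is_zero(self):
        score, n = cosine_score([(100.0, 1.0)], [(200.0, 1.0)], 0.01)
        assert score == 0.0 and n == 0

    def test_hand_computed_example(self):
        a = [(100.0, 1.0), (150.0, 0.25)]
        b = [(100.0, 0.25), (150.0, 1.0)]
        score, n = cosine_score(a, b, 0.01)
        assert score == pytest.approx(0.64, abs=1e-12)
        assert n == 2

    def test_symmetry_and_scale_invariance_100_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            m1, m2 = rng.integers(2, 9, 2)
            a = list(zip(np.sort(rng.uniform(50, 500, m1)).tolist(),
                         rng.uniform(0.1, 10, m1).tolist()))
            b = list(zip(np.sort(rng.uniform(50, 500, m2)).tolist(),
                         rng.uniform(0.1, 10, m2).tolist()))
            s_ab, n_ab = cosine_score(a, b, 0.5)
            s_ba, n_ba = cosine_score(b, a, 0.5)
            assert s_ab == pytest.approx(s_ba, abs=1e-12) and n_ab == n_ba
            scaled = [(mz, 7.3 * i) for mz, i in a]
            s_scaled, _ = cosine_score(scaled, b, 0.5)
            assert s_scaled == pytest.approx(s_ab, abs=1e-12)
            assert 0.0 <= s_ab <= 1.0
            assert n_ab <= min(len(a), len(b))

    def test_greedy_close_to_optimal_pairing(self):
        rng = np.random.default_rng(23)
        agree = 0
        disagreements = []
        trials = 200
        for t in range(trials):
            m1, m2 = rng.integers(2, 7, 2)
            a = list(zip(rng.uniform(50, 80, m1).tolist(), rng.uniform(0.1, 10, m1).tolist()))
            b = list(zip(rng.uniform(50, 80, m2).tolist(), rng.uniform(0.1, 10, m2).tolist()))
            greedy, _ = cosine_score(a, b, 2.0)
            optimal = optimal_pairing_score(a, b, 2.0)
            assert greedy <= optimal + 1e-9
            if greedy == pytest.approx(optimal, abs=1e-9):
                agree += 1
            else:
                disagreements.append((t, greedy, optimal))
        # report, don't hide, the greedy-vs-optimal discrepancies
        assert agree >= 0.95 * trials, f"greedy/optimal disagreements: {disagreements}"

    def test_precursor_shift_enables_modified_match(self):
        a = [(110.0, 1.0)]
        b = [(100.0, 1.0)]
        score0, _ = cosine_score(a, b, 0.01)
        score1, n1 = cosine_score(a, b, 0.01, precursor_shift=10.0)
        assert score0 == 0.0
        assert score1 == pytest.approx(1.0, abs=1e-12) and n1 == 1

    def test_empty_spectrum_error(self):
        with pytest.raises(MetaboPipeError):
            cosine_score([], [(100.0, 1.0)], 0.01)
        with pytest.raises(MetaboPipeError):
            cosine_score([(100.0, 1.0)], [(100.0, 1.0)], 0.0)

    def test_spectral_match_invariants(self):
        ref = RefSpectrum("x", precursor_mz=100.0, peaks=[(50.0, 1.0)])
        with pytest.raises(ValidationError):
            SpectralMatch("q", ref, score=1.5, n_matched_peaks=1)


class TestLevel4:
    def _ec(self, mass):
        return EmpiricalCompound("E1", neutral_formula_mass=mass)

    def test_isomers_both_attach(self):
        ec = self._ec(180.0633776)
        compounds = [
            Compound("glc", "glucose", "C6H12O6", C6H12O6),
            Compound("fru", "fructose", "C6H12O6", C6H12O6),
        ]
        annotate_level4([ec], compounds, mz_tol_ppm=5.0)
        assert {a.compound_name for a in ec.annotations} == {"glucose", "fructose"}
        for a in ec.annotations:
            assert a.level == "4"
            assert abs(a.evidence["ppm_error"]) < 1.0

    def test_absent_neutral_mass_untouched(self):
        ec = self._ec(None)
        annotate_level4([ec], [Compound("glc", "glucose", "C6H12O6", C6H12O6)])
        assert ec.annotations == []

    def test_zero_tolerance_only_exact(self):
        ec = self._ec(C6H12O6)
        compounds = [
            Compound("exact", "exact", "C6H12O6", C6H12O6),
            Compound("near", "near", "", C6H12O6 + 1e-4),
        ]
        annotate_level4([ec], compounds, mz_tol_ppm=0.0)
        assert [a.compound_name for a in ec.annotations] == ["exact"]

    def test_empty_list_warns(self):
        with pytest.warns(UserWarning):
            annotate_level4([self._ec(100.0)], [])

    def test_idempotent(self):
        ec = self._ec(180.0633776)
        cpds = [Compound("glc", "glucose", "C6H12O6", C6H12O6)]
        annotate_level4([ec], cpds)
        annotate_level4([ec], cpds)
        assert len(ec.annotations) == 1


class TestLevel1b:
    def _ec(self):
        return EmpiricalCompound(
            "E1", ms1_features=[MS1Member("F1", "M0", "M+H[1+]", mz=181.0707, rtime=100.0)]
        )

    def test_match_within_windows(self):
        ec = self._ec()
        std = StandardEntry("glucose", mz=181.0706, rtime=101.0)
        annotate_level1b([ec], [std], mz_tol_ppm=10.0, rt_tol_s=5.0)
        assert len(ec.annotations) == 1
        ann = ec.annotations[0]
        assert ann.level == "1b"
        assert abs(ann.evidence["ppm_error"]) == pytest.approx(0.552, abs=0.01)
        assert ann.evidence["rt_error_s"] == pytest.approx(-1.0)

    def test_rt_gate(self):
        ec = self._ec()
        std = StandardEntry("glucose", mz=181.0706, rtime=200.0)
        annotate_level1b([ec], [std], mz_tol_ppm=10.0, rt_tol_s=5.0)
        assert ec.annotations == []

    def test_two_standards_sorted_by_combined_error(self):
        ec = self._ec()
        near = StandardEntry("near", mz=181.0707, rtime=100.1)
        far = StandardEntry("far", mz=181.0715, rtime=104.0)
        annotate_level1b([ec], [far, near], mz_tol_ppm=10.0, rt_tol_s=5.0)
        assert [a.compound_name for a in ec.annotations] == ["near", "far"]


class TestMapMS2:
    def _spectrum(self, precursor, rt):
        return MSSpectrum(
            peaks=[(50.0, 1.0), (60.0, 2.0)], ms_level=2,
            precursor_mz=precursor, retention_time=rt,
        )

    def _ec(self, iid, mz, rt):
        return EmpiricalCompound(
            iid, ms1_features=[MS1Member("F_" + iid, "M0", "M+H[1+]", mz=mz, rtime=rt)]
        )

    def test_attach_within_windows(self):
        ec = self._ec("E1", 181.0707, 100.0)
        _, unmatched = map_ms2_to_empcpds([self._spectrum(181.0708, 110.0)], [ec])
        assert unmatched == [] and len(ec.ms2_spectra) == 1

    def test_unmatched_retained(self):
        ec = self._ec("E1", 181.0707, 100.0)
        _, unmatched = map_ms2_to_empcpds([self._spectrum(500.0, 100.0)], [ec])
        assert len(unmatched) == 1 and ec.ms2_spectra == []

    def test_nearest_candidate_wins(self):
        near = self._ec("E1", 181.0707, 100.0)
        far = self._ec("E2", 181.0710, 125.0)
        spectrum = self._spectrum(181.0707, 101.0)
        map_ms2_to_empcpds([spectrum], [far, near])
        assert near.ms2_spectra == [spectrum]
        assert far.ms2_spectra == []


class TestLevel2And1a:
    def _ec_with_spectrum(self, ref, jitter=0.0):
        rng = np.random.default_rng(0)
        peaks = [(mz, i * (1 + jitter * rng.standard_normal())) for mz, i in ref.peaks]
        spectrum = MSSpectrum(
            peaks=peaks, ms_level=2, precursor_mz=ref.precursor_mz, retention_time=100.0
        )
        ec = EmpiricalCompound("E1", ms2_spectra=[spectrum])
        return ec

    def test_authentic_gives_level_1a(self):
        rng = np.random.default_rng(1)
        refs = _random_refs(rng, 5)
        for r in refs:
            r.is_authentic_standard = True
        ec = self._ec_with_spectrum(refs[0])
        annotate_level2_1a([ec], refs)
        assert ec.annotations[0].level == "1a"
        assert ec.annotations[0].score == pytest.approx(1.0, abs=1e-9)

    def test_external_gives_level_2(self):
        rng = np.random.default_rng(1)
        refs = _random_refs(rng, 5)
        ec = self._ec_with_spectrum(refs[0])
        annotate_level2_1a([ec], refs)
        assert ec.annotations[0].level == "2"

    def test_empty_library_warns(self):
        ec = EmpiricalCompound("E1")
        with pytest.warns(UserWarning):
            annotate_level2_1a([ec], [])

    def test_top1_recovery_jittered_library(self):
        refs, queries, truth = generate_spectral_library(
            n_compounds=20, peaks_per_spectrum=8, seed=13
        )
        correct = 0
        for q in queries:
            ec = EmpiricalCompound("Eq", ms2_spectra=[q])
            annotate_level2_1a([ec], refs, min_score=0.6, min_matched=3)
            if ec.annotations and (
                ec.annotations[0].compound_name
                == truth.spectrum_compounds[q.source_acquisition]
            ):
                correct += 1
        assert correct >= 19

    def test_min_matched_gate(self):
        ref = RefSpectrum("x", precursor_mz=200.0,
                          peaks=[(100.0, 1.0), (110.0, 1.0)])
        ec = self._ec_with_spectrum(ref)
        annotate_level2_1a([ec], [ref], min_matched=3)
        assert ec.annotations == []
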