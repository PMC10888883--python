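"""MS2 spectral similarity scoring.

Square-root-transformed modified cosine with greedy peak pairing:

1. Candidate pairs are peaks within ``frag_tol_da`` of each other, or — when a
   nonzero ``precursor_shift`` is given — within tolerance after shifting the
   second spectrum's peak by the precursor mass difference.
2. Pairs are consumed in descending raw intensity-product order; each peak is
   used at most once.
3. score = (sum over matched pairs of sqrt(Ia * Ib))^2 / (sum(Ia) * sum(Ib)),
   i.e. the squared cosine of the sqrt-intensity vectors under the pairing.

The score is in [0, 1]; identical spectra score exactly 1.  Greedy pairing is
standard practice; an exhaustive optimal-pairing oracle lives in the test
suite and discrepancies on random small spectra are reported there.
"""

from __future__ import annotations

from ..errors import MetaboPipeError


def _peaks_of(spectrum):
    peaks = getattr(spectrum, "peaks", spectrum)
    return [(float(m), float(i)) for m, i in peaks]


def cosine_score(a, b, frag_tol_da: float = 0.01, precursor_shift: float = 0.0):
    """Score two centroided spectra; returns ``(score, n_matched)``.

    ``a`` and ``b`` may be MSSpectrum/RefSpectrum objects or raw peak lists.
    Symmetric in its arguments and invariant to uniform intensity scaling.
    """
    if frag_tol_da <= 0:
        raise MetaboPipeError("frag_tol_da must be > 0")
    pa, pb = _peaks_of(a), _peaks_of(b)
    if not pa or not pb:
        raise MetaboPipeError("cannot score an empty spectrum")

    candidates = []
    for i, (mza, ia) in enumerate(pa):
        for j, (mzb, ib) in enumerate(pb):
            direct = abs(mza - mzb) <= frag_tol_da
            shifted = precursor_shift != 0.0 and abs(mza - (mzb + precursor_shift)) <= frag_tol_da
            if direct or shifted:
                candidates.append((ia * ib, i, j))
    # descending intensity product; deterministic tie-break on indices
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b = set(), set()
    num = 0.0
    n_matched = 0
    for prod, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        num += prod ** 0.5
        n_matched += 1
    denom = sum(i for _, i in pa) * sum(i for _, i in pb)
    if denom <= 0:
        return 0.0, 0
    score = num * num / denom
    return min(score, 1.0), n_matched
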