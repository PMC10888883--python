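"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the production code paths: grid partitioning is done
by exhaustive search with permutation backtracking, precursor lookup by
linear scan, and peak pairing by exhaustive matching enumeration.
"""

from __future__ import annotations

import itertools

from metabopipe.preannotation import C13_C12, MAX_ISOTOPES


# ---------------------------------------------------------------------------
# Exhaustive grid partition search
# ---------------------------------------------------------------------------

def _oracle_cells(relations):
    """(iso_k, adduct) cells per charge, in the same preference order."""
    adducts = [r for r in relations if r.kind == "adduct"]
    by_charge = {}
    for z in sorted({a.charge for a in adducts}):
        z_adducts = sorted((a for a in adducts if a.charge == z), key=lambda a: not a.anchor)
        cells = [(k, a) for a in z_adducts for k in range(MAX_ISOTOPES + 1)]
        by_charge[z] = cells
    return by_charge


def _cell_mz(cell, M):
    k, adduct = cell
    return (M + adduct.delta_mz + k * C13_C12) / adduct.charge


def oracle_subset_consistent(feats, relations, mz_tol_ppm, rt_tol_s):
    """Minimal total ppm error over valid grid assignments of ALL feats, or None.

    feats: list of objects with .mz and .rtime (or .rt).  Consistency rule:
    single charge, neutral mass anchored at the lowest-m/z member's cell,
    distinct cells, each within ppm tolerance of its theoretical m/z, and
    rt span <= rt_tol_s.  Total error rounded to 1e-6 ppm.
    """
    if len(feats) < 2:
        return None
    rts = [getattr(f, "rtime", getattr(f, "rt", None)) for f in feats]
    if max(rts) - min(rts) > rt_tol_s + 1e-12:
        return None
    feats = sorted(feats, key=lambda f: (f.mz, getattr(f, "id", getattr(f, "fid", ""))))
    f0, rest = feats[0], feats[1:]
    best = None
    for z, cells in _oracle_cells(relations).items():
        for seed_cell in cells:
            k0, adduct0 = seed_cell
            M = f0.mz * adduct0.charge - adduct0.delta_mz - k0 * C13_C12
            if M < 1.0:
                continue
            other_cells = [c for c in cells if c != seed_cell]
            # backtracking over injective assignments of the remaining feats
            def search(i, used, total):
                nonlocal best
                if i == len(rest):
                    t = round(total, 6)
                    if best is None or t < best:
                        best = t
                    return
                f = rest[i]
                for ci, c in enumerate(other_cells):
                    if ci in used:
                        continue
                    theo = _cell_mz(c, M)
                    ppm = abs(f.mz - theo) / theo * 1e6
                    if ppm <= mz_tol_ppm:
                        search(i + 1, used | {ci}, total + ppm)

            search(0, frozenset(), 0.0)
    return best


def oracle_best_partition(feats, relations, mz_tol_ppm, rt_tol_s):
    """Exhaustive optimal partition into consistent grids + singletons.

    Returns a set of frozensets of feature ids (the grouped grids only),
    maximizing (grouped features, sum C(n,2)) then minimizing total ppm
    error, then lexicographically smallest partition.
    """
    n = len(feats)
    ids = [getattr(f, "id", getattr(f, "fid", "")) for f in feats]
    consistent = {}
    for mask in range(1, 1 << n):
        if bin(mask).count("1") < 2:
            continue
        sub = [feats[i] for i in range(n) if mask >> i & 1]
        err = oracle_subset_consistent(sub, relations, mz_tol_ppm, rt_tol_s)
        if err is not None:
            consistent[mask] = err

    best = {"key": None, "partition": None}

    def canon(masks):
        return tuple(sorted(
            tuple(sorted(ids[i] for i in range(n) if m >> i & 1)) for m in masks
        ))

    def dfs(remaining, chosen, grouped, edges, err):
        if remaining == 0:
            key = (grouped, edges, -err)
            c = canon(chosen)
            if (best["key"] is None or key > best["key"]
                    or (key == best["key"] and c < best["partition"])):
                best["key"] = key
                best["partition"] = c
            return
        low = remaining & -remaining
        dfs(remaining ^ low, chosen, grouped, edges, err)  # singleton
        for mask, e in consistent.items():
            if mask & low and mask & remaining == mask:
                size = bin(mask).count("1")
                dfs(remaining ^ mask, chosen + [mask],
                    grouped + size, edges + size * (size - 1) // 2, err + e)

    dfs((1 << n) - 1, [], 0, 0, 0.0)
    return set(frozenset(g) for g in best["partition"])


# ---------------------------------------------------------------------------
# Linear-scan precursor lookup
# ---------------------------------------------------------------------------

def linear_scan_query(refs, mz, mz_tol_ppm):
    """References whose closed ppm window (around their precursor) contains mz."""
    tol = mz_tol_ppm * 1e-6
    return [
        r for r in refs
        if r.precursor_mz is not None
        and r.precursor_mz * (1 - tol) <= mz <= r.precursor_mz * (1 + tol)
    ]


# ---------------------------------------------------------------------------
# Optimal peak pairing
# ---------------------------------------------------------------------------

def optimal_pairing_score(peaks_a, peaks_b, frag_tol_da, precursor_shift=0.0):
    """Exhaustive optimal pairing maximizing sum sqrt(Ia*Ib); returns score.

    Only feasible for small spectra (<= ~7 peaks each).
    """
    pa = [(float(m), float(i)) for m, i in peaks_a]
    pb = [(float(m), float(i)) for m, i in peaks_b]
    allowed = {}
    for i, (mza, _) in enumerate(pa):
        for j, (mzb, _) in enumerate(pb):
            if abs(mza - mzb) <= frag_tol_da or (
                precursor_shift != 0.0 and abs(mza - (mzb + precursor_shift)) <= frag_tol_da
            ):
                allowed.setdefault(i, []).append(j)

    best = 0.0

    def search(i, used, total):
        nonlocal best
        if i == len(pa):
            best = max(best, total)
            return
        search(i + 1, used, total)  # leave peak i unmatched
        for j in allowed.get(i, ()):
            if j not in used:
                search(i + 1, used | {j}, total + (pa[i][1] * pb[j][1]) ** 0.5)

    search(0, frozenset(), 0.0)
    denom = sum(i for _, i in pa) * sum(i for _, i in pb)
    return best * best / denom if denom > 0 else 0.0
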