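"""Interval-tree index over reference precursor m/z windows.

Each reference contributes the closed interval ``[mz*(1-tol), mz*(1+tol)]``
(tol = ppm * 1e-6).  A point query returns every reference whose window
contains the query m/z — equivalently, every reference within its own ppm
window of the query (ppm computed against the reference m/z, closed bounds).

The tree is a classic static centered interval tree: O(n log n) construction,
O(log n + k) stabbing queries.  Results are always identical to a linear scan
(property-tested against one).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass


class _TreeNode:
    __slots__ = ("center", "by_start", "by_end", "left", "right")

    def __init__(self, center, overlapping):
        self.center = center
        self.by_start = sorted(overlapping, key=lambda iv: iv[0])
        self.by_end = sorted(overlapping, key=lambda iv: -iv[1])
        self.left = None
        self.right = None


class IntervalTree:
    """Static centered interval tree over (start, end, payload) triples."""

    def __init__(self, intervals):
        """intervals: iterable of (start, end, payload); closed on both ends."""
        ivs = [(float(s), float(e), p) for s, e, p in intervals]
        for s, e, _ in ivs:
            if e < s:
                raise ValueError(f"interval end {e} < start {s}")
        self._n = len(ivs)
        self._root = self._build(ivs) if ivs else None

    def __len__(self):
        return self._n

    @staticmethod
    def _build(ivs):
        center = statistics.median([(s + e) / 2.0 for s, e, _ in ivs])
        left, right, mid = [], [], []
        for iv in ivs:
            if iv[1] < center:
                left.append(iv)
            elif iv[0] > center:
                right.append(iv)
            else:
                mid.append(iv)
        node = _TreeNode(center, mid)
        if left:
            node.left = IntervalTree._build(left)
        if right:
            node.right = IntervalTree._build(right)
        return node

    def stab(self, point):
        """All payloads whose [start, end] contains ``point`` (closed)."""
        out = []
        node = self._root
        while node is not None:
            if point < node.center:
                for s, e, p in node.by_start:
                    if s > point:
                        break
                    out.append(p)
                node = node.left
            elif point > node.center:
                for s, e, p in node.by_end:
                    if e < point:
                        break
                    out.append(p)
                node = node.right
            else:
                out.extend(p for _, _, p in node.by_start)
                node = None
        return out


@dataclass
class PrecursorIndex:
    """ppm-window precursor index over a reference spectrum collection."""

    tree: IntervalTree
    mz_tol_ppm: float
    n_indexed: int
    n_skipped: int  # references lacking a precursor m/z

    def query(self, mz: float):
        """References whose closed ppm window contains ``mz``, sorted stably."""
        hits = self.tree.stab(float(mz))
        hits.sort(key=lambda r: (r.precursor_mz, r.compound_name))
        return hits


def build_precursor_index(refs, mz_tol_ppm: float = 10.0) -> PrecursorIndex:
    """Index reference spectra by precursor m/z ppm window.

    References without a precursor m/z are excluded; their count is reported
    on the returned index.
    """
    tol = mz_tol_ppm * 1e-6
    intervals = []
    skipped = 0
    for r in refs:
        if getattr(r, "precursor_mz", None) is None:
            skipped += 1
            continue
        mz = r.precursor_mz
        intervals.append((mz * (1 - tol), mz * (1 + tol), r))
    return PrecursorIndex(
        tree=IntervalTree(intervals),
        mz_tol_ppm=mz_tol_ppm,
        n_indexed=len(intervals),
        n_skipped=skipped,
    )
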