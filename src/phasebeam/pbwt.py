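"""Positional Burrows-Wheeler transform: build, interval mapping, matching.

The PBWT keeps, for every site m, the permutation of haplotypes obtained by
sorting their *reversed prefixes* ``x[m-1], x[m-2], ...`` lexicographically
(stable, ties by haplotype index).  Haplotypes sharing a pattern that ends
just before site m then occupy a contiguous interval of permuted rows, and
extending the pattern by one allele maps that interval through an FM-index
style occurrence count in O(1) — independent of panel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "Interval",
    "Match",
    "PbwtIndex",
    "build_pbwt",
    "map_interval",
    "interval_frequency",
    "set_maximal_matches",
]

OCC_STRIDE = 64  # checkpoint spacing (haplotypes) for occurrence counts


@dataclass(frozen=True)
class Interval:
    """Contiguous block of permuted rows at a given site (inclusive bounds)."""

    site: int
    lo: int
    hi: int

    @property
    def empty(self) -> bool:
        return self.lo > self.hi

    @property
    def size(self) -> int:
        return 0 if self.empty else self.hi - self.lo + 1


@dataclass(frozen=True, order=True)
class Match:
    """Agreement segment between a query and one panel haplotype.

    ``start`` inclusive, ``end`` exclusive; query and haplotype agree on
    ``[start, end)`` with missing query positions agreeing with anything.
    """

    start: int
    end: int
    hap: int

    @property
    def length(self) -> int:
        return self.end - self.start


class _OccColumn:
    """Rank support over one permuted allele column.

    Bits are the alleles in prefix order at a site; checkpoints store the
    number of set bits before every multiple of ``stride`` and gaps are
    closed with popcounts over the packed bytes.
    """

    __slots__ = ("n", "stride", "_bytes", "_cp")

    def __init__(self, y: np.ndarray, stride: int = OCC_STRIDE):
        if stride % 8:
            raise ValueError("occurrence-count stride must be a multiple of 8")
        self.n = len(y)
        self.stride = stride
        packed = np.packbits(y)
        self._bytes = packed.tobytes()
        counts = np.zeros(len(packed) + 1, dtype=np.int64)
        np.cumsum(np.unpackbits(packed).reshape(-1, 8).sum(axis=1), out=counts[1:])
        self._cp = counts[:: stride // 8]  # ones before each checkpoint

    def rank1(self, k: int) -> int:
        """Number of set bits among positions < k."""
        t = k // self.stride
        base = t * self.stride
        r = int(self._cp[t])
        if k > base:
            word = int.from_bytes(self._bytes[base // 8 : (k + 7) // 8], "big")
            r += (word >> ((-k) % 8)).bit_count()
        return r

    @property
    def c0(self) -> int:
        return self.n - self.rank1(self.n)


class PbwtIndex:
    """PBWT of a haplotype panel.

    Attributes
    ----------
    prefix:
        list of M+1 permutations; ``prefix[m]`` sorts haplotypes by reversed
        prefix ending before site m (``prefix[0]`` is the identity).
    divergence:
        ``divergence[m][i]`` is the start of the longest match ending at m
        between permuted rows i and i-1 (m for row 0, values in [0, m]).
    """

    def __init__(self, n_haps: int, n_sites: int, prefix, divergence, cols):
        self.n_haps = n_haps
        self.n_sites = n_sites
        self.prefix = prefix
        self.divergence = divergence
        self._cols = cols

    def c0(self, m: int) -> int:
        """Count of allele-0 haplotypes at site m."""
        return self._cols[m].c0

    def occ(self, m: int, allele: int, k: int) -> int:
        """Occurrences of ``allele`` among the first k permuted rows at site m."""
        r1 = self._cols[m].rank1(k)
        return r1 if allele else k - r1

    def full_interval(self, m: int = 0) -> Interval:
        """Whole-panel interval (the empty pattern) at site m."""
        return Interval(m, 0, self.n_haps - 1)


def _segment_max(d: np.ndarray, idx: np.ndarray, sentinel: int) -> np.ndarray:
    """Divergence of each group member: max of d over (previous member, member]."""
    if idx.size == 0:
        return np.empty(0, dtype=d.dtype)
    starts = np.concatenate(([0], idx[:-1] + 1))
    out = np.maximum.reduceat(d[: idx[-1] + 1], starts)
    out[0] = sentinel  # first row of the group has no predecessor carried over
    return out


def build_pbwt(panel: HaplotypePanel, stride: int = OCC_STRIDE) -> PbwtIndex:
    """Build the PBWT of ``panel`` (prefix/divergence arrays + rank index).

    Runs Durbin's forward sweep: at each site the current permutation is
    stably partitioned by allele (zeros first), which keeps reversed
    prefixes sorted; divergence values are carried along as running maxima.
    """
    n, m_sites = panel.n_haps, panel.n_sites
    a = np.arange(n, dtype=np.int64)
    d = np.zeros(n, dtype=np.int64)
    prefix = [a]
    divergence = [d]
    cols = []
    for m in range(m_sites):
        y = panel.column(m)[a]
        if y.size and y.max() > 1:  # pragma: no cover - guarded by panel ctor
            raise ValueError("panel is not biallelic")
        cols.append(_OccColumn(y, stride=stride))
        zeros = np.flatnonzero(y == 0)
        ones = np.flatnonzero(y == 1)
        a = np.concatenate((a[zeros], a[ones]))
        d = np.concatenate(
            (_segment_max(d, zeros, m + 1), _segment_max(d, ones, m + 1))
        )
        prefix.append(a)
        divergence.append(d)
    return PbwtIndex(n, m_sites, prefix, divergence, cols)


def map_interval(index: PbwtIndex, iv: Interval) -> tuple[Interval, Interval]:
    """Extend the pattern of ``iv`` by one site, for both possible alleles.

    ``iv`` lives at site m (pattern over sites ending before m); the result
    is the pair of intervals at site m+1 for the pattern extended with
    allele 0 and allele 1.  Either output may be empty.
    """
    if iv.empty:
        raise ValueError("cannot map an empty interval")
    m = iv.site
    if not 0 <= m < index.n_sites:
        raise ValueError(f"interval site {m} out of range for {index.n_sites} sites")
    c0 = index.c0(m)
    lo0 = index.occ(m, 0, iv.lo)
    hi0 = index.occ(m, 0, iv.hi + 1) - 1
    lo1 = c0 + index.occ(m, 1, iv.lo)
    hi1 = c0 + index.occ(m, 1, iv.hi + 1) - 1
    return Interval(m + 1, lo0, hi0), Interval(m + 1, lo1, hi1)


def interval_frequency(index: PbwtIndex, iv: Interval) -> float:
    """Panel frequency of the pattern an interval represents (size / N)."""
    return iv.size / index.n_haps


def _maximal_runs(agree: np.ndarray):
    """Per-haplotype maximal True runs of a boolean (N, M) matrix."""
    n, m = agree.shape
    pad = np.zeros((n, 1), dtype=bool)
    ext = np.hstack((pad, agree, pad))
    diff = ext[:, 1:].astype(np.int8) - ext[:, :-1].astype(np.int8)
    hs, ss = np.nonzero(diff == 1)
    he, es = np.nonzero(diff == -1)
    # starts and ends pair up in order within each haplotype
    return hs, ss, es


def set_maximal_matches(
    index: PbwtIndex, panel: HaplotypePanel, query
) -> list[Match]:
    """All set-maximal matches of ``query`` against the panel.

    A match is an agreement segment (missing query alleles, encoded
    negative, agree with anything) that is not strictly contained in any
    other agreement segment of the same query.  All haplotypes attaining a
    maximal segment are reported, sorted by (start, end, hap).

    The heavy lifting is a vectorised run-length sweep over the agreement
    matrix; the PBWT index pins the panel this query was matched against
    (and supplies N for downstream frequency use).
    """
    q = np.asarray(query, dtype=np.int16).ravel()
    if q.shape[0] != panel.n_sites:
        raise ValueError(
            f"query length {q.shape[0]} != panel sites {panel.n_sites}"
        )
    if index.n_sites != panel.n_sites or index.n_haps != panel.n_haps:
        raise ValueError("index/panel shape mismatch")
    if panel.n_sites == 0:
        return []
    agree = (panel.matrix == q) | (q < 0)[np.newaxis, :]
    hs, ss, es = _maximal_runs(agree)
    if hs.size == 0:
        return []
    # keep only set-maximal segments: for each start the longest end wins,
    # then discard segments contained in one with an earlier start
    seg_end: dict[int, int] = {}
    for s, e in zip(ss.tolist(), es.tolist()):
        if e > seg_end.get(s, -1):
            seg_end[s] = e
    kept: set[tuple[int, int]] = set()
    best_e = -1
    for s in sorted(seg_end):
        e = seg_end[s]
        if e > best_e:
            kept.add((s, e))
            best_e = e
    out = [
        Match(int(s), int(e), int(h))
        for h, s, e in zip(hs.tolist(), ss.tolist(), es.tolist())
        if (s, e) in kept
    ]
    out.sort()
    return out
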