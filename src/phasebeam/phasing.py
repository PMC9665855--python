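"""Reference-based phasing by beam search over a condensed reference.

Each target sample is phased against the K reference haplotypes most
compatible with its genotypes, restricted to the sample's typed sites (the
*condensed reference*).  A diplotype hypothesis is a pair of PBWT intervals
— one per haplotype under construction — so extending a hypothesis by one
site is two O(1) interval mappings instead of a scan over haplotypes.

The path probability model is a conditional-copying (Li-Stephens flavoured)
score: extensions supported by the panel are free; an extension that empties
its interval restarts from the whole panel and is charged a recombination
penalty rho together with a mismatch penalty eps.  Probabilities are kept as
a significand in (0, 1] times a shared power-of-two exponent; the exponent
is only touched when the best significand drops below 2**-64, so repeated
sums stay exact in ordinary double arithmetic — no log-space approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel, MISSING
from .pbwt import PbwtIndex, build_pbwt
from .reconcile import TargetRefAlignment

__all__ = [
    "PhasingParams",
    "CondensedReference",
    "PhasedSample",
    "select_k_best",
    "build_condensed_reference",
    "phase_sample",
    "reverse_phase",
    "USAGE_PHASED",
    "USAGE_HOM_FORCED",
    "USAGE_MISSING_DEFERRED",
    "USAGE_LABELS",
]

USAGE_PHASED = 0
USAGE_HOM_FORCED = 1
USAGE_MISSING_DEFERRED = 2
USAGE_LABELS = {
    USAGE_PHASED: "phased",
    USAGE_HOM_FORCED: "hom_forced",
    USAGE_MISSING_DEFERRED: "missing_deferred",
}

_RENORM_THRESHOLD = 2.0**-64


@dataclass
class PhasingParams:
    """Tunable parameters of the beam search.

    k:
        number of reference haplotypes selected per sample ("max" = all).
    beam_width:
        number of diplotype hypotheses kept per site (P).
    delta:
        length of the phase-decision history used in the merge rule.
    recomb_penalty / mismatch_penalty:
        multiplicative penalties for an interval restart (see module docs).
    """

    k: int | str = 10_000
    beam_width: int = 128
    delta: int = 24
    iterations: int = 1
    recomb_penalty: float = 0.008
    mismatch_penalty: float = 0.003
    pre_phasing: bool = False
    reverse_phasing: bool = True

    def __post_init__(self) -> None:
        if self.k != "max" and int(self.k) < 1:
            raise ValueError("k must be >= 1 or 'max'")
        if self.beam_width < 1 or self.delta < 1 or self.iterations < 1:
            raise ValueError("beam_width, delta and iterations must be >= 1")
        for p in (self.recomb_penalty, self.mismatch_penalty):
            if not 0.0 < p < 1.0:
                raise ValueError("penalties must lie strictly in (0, 1)")


@dataclass
class CondensedReference:
    """K selected haplotypes restricted to one sample's typed shared sites."""

    sample_id: str
    selected: np.ndarray  # global reference haplotype indices
    panel: HaplotypePanel  # restricted + recoded to target orientation
    site_map: np.ndarray  # condensed index -> global reference site index
    index: PbwtIndex


@dataclass
class PhasedSample:
    """Phasing result over the sample's typed (condensed) sites.

    hap_a/hap_b contain -1 at missing_deferred sites; ``confidence`` is NaN
    outside heterozygous sites and lies in [0.5, 1] at them.
    """

    sample_id: str
    hap_a: np.ndarray
    hap_b: np.ndarray
    confidence: np.ndarray
    usage: np.ndarray

    def haplotypes(self) -> np.ndarray:
        return np.vstack((self.hap_a, self.hap_b))


def select_k_best(ref_panel: HaplotypePanel, target_genotypes, k) -> np.ndarray:
    """Indices of the K reference haplotypes most compatible with a target.

    The distance of a haplotype is the number of sites where its allele
    contradicts a homozygous target genotype; heterozygous and missing
    genotypes constrain nothing.  Ties break by ascending haplotype index
    and the returned selection is sorted ascending.
    """
    g = np.asarray(target_genotypes).ravel()
    if g.shape[0] != ref_panel.n_sites:
        raise ValueError("genotype vector length != panel sites")
    if ref_panel.n_sites == 0:
        raise ValueError(
            "no shared sites between target and reference; check variant reconciliation"
        )
    n = ref_panel.n_haps
    k = n if k == "max" else min(int(k), n)
    mat = ref_panel.matrix
    dist = mat[:, g == 0].sum(axis=1) + (1 - mat[:, g == 2]).sum(axis=1)
    order = np.argsort(dist, kind="stable")  # ties by haplotype index
    return np.sort(order[:k])


def build_condensed_reference(
    ref_panel: HaplotypePanel,
    alignment: TargetRefAlignment,
    selected,
    sample_id: str,
) -> CondensedReference:
    """Slice the reference down to ``selected`` haplotypes at shared sites.

    Alleles are recoded into the target's orientation at swap sites, and a
    PBWT is built over the restricted panel.
    """
    selected = np.asarray(selected)
    if selected.size == 0:
        raise ValueError("empty haplotype selection for condensed reference")
    shared = alignment.shared_ref_idx
    flips = alignment.shared_flip
    sub = ref_panel.restrict(hap_idx=selected, site_idx=shared, flip=flips)
    return CondensedReference(
        sample_id=sample_id,
        selected=selected,
        panel=sub,
        site_map=np.asarray(shared),
        index=build_pbwt(sub),
    )


# ----------------------------------------------------------------------
# beam search


class _Beam:
    """One forward beam pass; returns terminal states and traceback chains.

    A state is ``(ivA, ivB, mantissa, hist, node)`` with intervals as
    (lo, hi) tuples, ``hist`` the last <=delta phase decisions and ``node``
    a linked (bit, parent) chain recording every decision for traceback.
    """

    def __init__(self, index: PbwtIndex, params: PhasingParams):
        self.idx = index
        self.params = params
        self.n = index.n_haps

    def run(self, genotypes: np.ndarray):
        idx, n = self.idx, self.n
        p_keep = self.params.beam_width
        delta = self.params.delta
        restart_pen = self.params.recomb_penalty * self.params.mismatch_penalty
        states = [((0, n - 1), (0, n - 1), 1.0, (), None)]
        scale_exp = 0
        het_sites: list[int] = []

        for m, g in enumerate(genotypes):
            col = idx._cols[m]
            c0 = col.c0
            rank1 = col.rank1
            mono = None
            if c0 == n:
                mono = 0
            elif c0 == 0:
                mono = 1

            def extend(iv, a):
                lo, hi = iv
                r1lo = rank1(lo)
                r1hi = rank1(hi + 1)
                if (mono if mono is not None else a) == 0:
                    lo2, hi2 = lo - r1lo, hi - r1hi
                else:
                    lo2, hi2 = c0 + r1lo, c0 + r1hi - 1
                if mono is not None or lo2 <= hi2:
                    return (lo2, hi2), 1.0
                # interval died: recombination restart from the whole panel,
                # charged rho for the restart and eps for the local mismatch
                full = (0, c0 - 1) if a == 0 else (c0, n - 1)
                return full, restart_pen

            new: list[tuple] = []
            if g == 0 or g == 2:
                a = int(g) >> 1
                for iva, ivb, mant, hist, node in states:
                    na, fa = extend(iva, a)
                    nb, fb = extend(ivb, a)
                    new.append((na, nb, mant * fa * fb, hist, node))
            elif g == 1:
                for iva, ivb, mant, hist, node in states:
                    for bit in (0, 1):
                        na, fa = extend(iva, bit)
                        nb, fb = extend(ivb, 1 - bit)
                        new.append(
                            (
                                na,
                                nb,
                                mant * fa * fb,
                                (hist + (bit,))[-delta:],
                                (bit, node),
                            )
                        )
                het_sites.append(m)
            elif g == MISSING:
                for iva, ivb, mant, hist, node in states:
                    las = []
                    lbs = []
                    for iv, acc in ((iva, las), (ivb, lbs)):
                        lo, hi = iv
                        r1lo = rank1(lo)
                        r1hi = rank1(hi + 1)
                        ch0 = (lo - r1lo, hi - r1hi)
                        ch1 = (c0 + r1lo, c0 + r1hi - 1)
                        for ch in (ch0, ch1):
                            if ch[0] <= ch[1]:
                                acc.append((ch, (ch[1] - ch[0] + 1) / n))
                    for na, fa in las:
                        for nb, fb in lbs:
                            new.append((na, nb, mant * fa * fb, hist, node))
            else:
                raise ValueError(f"invalid genotype value {g} at site {m}")

            # merge states identical in interval pair and delta-history
            merged: dict[tuple, list] = {}
            for iva, ivb, mant, hist, node in new:
                key = (iva, ivb, hist)
                cur = merged.get(key)
                if cur is None:
                    merged[key] = [mant, mant, node]
                else:
                    cur[0] += mant
                    if mant > cur[1]:  # traceback follows the dominant branch
                        cur[1] = mant
                        cur[2] = node
            pruned = sorted(
                (
                    (iva, ivb, vals[0], hist, vals[2])
                    for (iva, ivb, hist), vals in merged.items()
                    if vals[0] > 0.0
                ),
                key=lambda s: (-s[2], s[3]),
            )[:p_keep]
            if not pruned:
                raise RuntimeError(
                    "beam search lost all states; this cannot happen with "
                    "a positive recombination penalty"
                )
            states = pruned
            mx = states[0][2]
            if mx < _RENORM_THRESHOLD:
                _, e = math.frexp(mx)
                f = math.ldexp(1.0, -e)
                states = [
                    (iva, ivb, mant * f, hist, node)
                    for iva, ivb, mant, hist, node in states
                ]
                scale_exp += e

        return states, scale_exp, het_sites


def _chain_bits(node, n_hets: int) -> list[int]:
    bits = []
    while node is not None:
        bits.append(node[0])
        node = node[1]
    bits.reverse()
    assert len(bits) == n_hets
    return bits


def _finalise(genotypes, states, het_sites, sample_id) -> PhasedSample:
    m_sites = len(genotypes)
    hap_a = np.full(m_sites, -1, dtype=np.int8)
    hap_b = np.full(m_sites, -1, dtype=np.int8)
    conf = np.full(m_sites, np.nan)
    usage = np.full(m_sites, USAGE_PHASED, dtype=np.int8)

    hom = (genotypes == 0) | (genotypes == 2)
    hap_a[hom] = hap_b[hom] = genotypes[hom] // 2
    usage[hom] = USAGE_HOM_FORCED
    usage[genotypes == MISSING] = USAGE_MISSING_DEFERRED

    if het_sites:
        n_hets = len(het_sites)
        best = states[0]  # states arrive sorted by (-mantissa, history)
        chosen = _chain_bits(best[4], n_hets)
        total = 0.0
        agree = np.zeros(n_hets)
        for iva, ivb, mant, hist, node in states:
            total += mant
            bits = _chain_bits(node, n_hets)
            for t in range(n_hets):
                if bits[t] == chosen[t]:
                    agree[t] += mant
        for t, m in enumerate(het_sites):
            hap_a[m] = chosen[t]
            hap_b[m] = 1 - chosen[t]
            conf[m] = min(1.0, max(0.5, agree[t] / total))
    return PhasedSample(sample_id, hap_a, hap_b, conf, usage)


def phase_sample(
    condensed: CondensedReference,
    genotypes,
    params: PhasingParams | None = None,
) -> PhasedSample:
    """Phase one sample's genotypes against its condensed reference.

    Runs the beam search described in the module docstring and tracebacks
    the highest-probability terminal state.  Per-het confidences are the
    probability mass of terminal states agreeing with the chosen
    orientation, normalised by the total terminal mass.
    """
    params = params or PhasingParams()
    g = np.asarray(genotypes, dtype=np.int8).ravel()
    if g.shape[0] != condensed.panel.n_sites:
        raise ValueError("genotype vector length != condensed sites")
    bad = ~np.isin(g, (0, 1, 2, MISSING))
    if bad.any():
        raise ValueError(f"invalid genotype value {g[bad][0]} in input")

    result = _finalise(
        g, *_run_beam(condensed, g, params), condensed.sample_id
    )
    if params.pre_phasing:
        # coarse seeding pass: a quarter-width beam whose agreement only
        # reinforces confidences, never changes the phased haplotypes
        coarse_params = PhasingParams(
            k=params.k,
            beam_width=max(1, params.beam_width // 4),
            delta=params.delta,
            recomb_penalty=params.recomb_penalty,
            mismatch_penalty=params.mismatch_penalty,
        )
        coarse = _finalise(
            g, *_run_beam(condensed, g, coarse_params), condensed.sample_id
        )
        het = g == 1
        agree = het & (coarse.hap_a == result.hap_a)
        result.confidence[agree] = np.maximum(
            result.confidence[agree], coarse.confidence[agree]
        )
    return result


def _run_beam(condensed, g, params):
    states, _scale, het_sites = _Beam(condensed.index, params).run(g)
    return states, het_sites


def _finalise_wrapper(*a):  # pragma: no cover - compat shim
    return _finalise(*a)


def score_diplotype(
    condensed: CondensedReference, genotypes, hap_a, hap_b,
    params: PhasingParams,
) -> float:
    """Log path probability of a fully specified diplotype under the model.

    Walks both haplotypes through the PBWT with the same extension and
    penalty rules as the beam; at missing sites the higher-frequency branch
    is taken (deterministic tie toward allele 0).
    """
    idx = condensed.index
    n = idx.n_haps
    restart = math.log(params.recomb_penalty * params.mismatch_penalty)
    lp = 0.0
    iv_a = (0, n - 1)
    iv_b = (0, n - 1)
    for m in range(len(genotypes)):
        col = idx._cols[m]
        c0 = col.c0
        mono = 0 if c0 == n else (1 if c0 == 0 else None)
        nxt = []
        for iv, a in ((iv_a, hap_a[m]), (iv_b, hap_b[m])):
            lo, hi = iv
            r1lo = col.rank1(lo)
            r1hi = col.rank1(hi + 1)
            ch0 = (lo - r1lo, hi - r1hi)
            ch1 = (c0 + r1lo, c0 + r1hi - 1)
            if a < 0 and mono is None:
                s0 = max(0, ch0[1] - ch0[0] + 1)
                s1 = max(0, ch1[1] - ch1[0] + 1)
                ch, sz = (ch0, s0) if s0 >= s1 else (ch1, s1)
                lp += math.log(sz / n)
                nxt.append(ch)
                continue
            aa = mono if mono is not None else int(a)
            ch = ch0 if aa == 0 else ch1
            if mono is None and ch[0] > ch[1]:
                lp += restart
                ch = (0, c0 - 1) if aa == 0 else (c0, n - 1)
            nxt.append(ch)
        iv_a, iv_b = nxt
    return lp


def reverse_phase(
    condensed: CondensedReference,
    genotypes,
    forward_result: PhasedSample,
    params: PhasingParams | None = None,
) -> PhasedSample:
    """Second pass over the site-reversed condensed reference.

    The reverse beam explores the diplotype space from the other end and
    proposes alternative orientation transitions between consecutive het
    sites.  Each disagreeing transition is adopted (greedily, left to
    right) only if it increases the model's own path probability, so the
    combined result never scores worse than the forward pass.  Where a
    reverse transition wins, its confidence replaces the forward one.
    Disabled => returns the forward result unchanged.
    """
    params = params or PhasingParams()
    if not params.reverse_phasing:
        return forward_result
    g = np.asarray(genotypes, dtype=np.int8).ravel()
    het_sites = np.flatnonzero(g == 1)
    if het_sites.size < 2:
        return forward_result
    rev_panel = HaplotypePanel(
        condensed.panel.matrix[:, ::-1], site_ids=condensed.panel.site_ids[::-1]
    )
    rev_condensed = CondensedReference(
        sample_id=condensed.sample_id,
        selected=condensed.selected,
        panel=rev_panel,
        site_map=condensed.site_map[::-1],
        index=build_pbwt(rev_panel),
    )
    rev = phase_sample(rev_condensed, g[::-1], params)
    r_a = rev.hap_a[::-1].copy()
    r_conf = rev.confidence[::-1].copy()

    of = forward_result.hap_a[het_sites]
    orv = r_a[het_sites]
    trans_f = of[1:] ^ of[:-1]
    trans_r = orv[1:] ^ orv[:-1]
    disagree = np.flatnonzero(trans_f != trans_r)
    if disagree.size == 0:
        return forward_result

    bits = of.copy()
    hap_a = forward_result.hap_a.copy()
    hap_b = forward_result.hap_b.copy()
    cur = score_diplotype(condensed, g, hap_a, hap_b, params)
    adopted = np.zeros(het_sites.size, dtype=bool)
    for i in disagree:
        cand = bits.copy()
        cand[i + 1 :] ^= 1  # flipping one transition flips the downstream chain
        ca, cb = hap_a.copy(), hap_b.copy()
        ca[het_sites] = cand
        cb[het_sites] = 1 - cand
        sc = score_diplotype(condensed, g, ca, cb, params)
        if sc > cur:
            bits, hap_a, hap_b, cur = cand, ca, cb, sc
            adopted[i + 1] = True
    conf = forward_result.confidence.copy()
    conf[het_sites[adopted]] = r_conf[het_sites[adopted]]
    return PhasedSample(
        forward_result.sample_id, hap_a, hap_b, conf, forward_result.usage
    )
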