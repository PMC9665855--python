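"""Target-versus-reference variant reconciliation and PAR splitting.

Array manifests and reference panels frequently disagree on which allele is
REF: a target A/C variant may appear as C/A in the panel (ref/alt swap), or
as T/G when the array reported the opposite strand (strand flip).  Both are
recoverable by re-orienting the 0/1 allele encoding, provided the user opts
in; strand-ambiguous SNVs (A/T, C/G) are never auto-flipped because a flip
is indistinguishable from a swap for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .panel import VariantRecord

__all__ = [
    "MatchClass",
    "TargetRefAlignment",
    "reconcile_variants",
    "split_par_regions",
    "PAR_REGIONS",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Pseudo-autosomal regions on chromosome X, half-open 1-based [start, end)
# per genome build; overridable wherever they are consumed.
PAR_REGIONS = {
    "GRCh37": {"PAR1": (60_001, 2_699_521), "PAR2": (154_931_044, 155_260_561)},
    "GRCh38": {"PAR1": (10_001, 2_781_480), "PAR2": (155_701_383, 156_030_896)},
}


class MatchClass(str, Enum):
    SHARED = "shared"
    SHARED_REFALT_SWAP = "shared_refalt_swap"
    SHARED_STRAND_FLIP = "shared_strand_flip"
    SHARED_SWAP_AND_FLIP = "shared_swap_and_flip"
    TARGET_ONLY = "target_only"
    EXCLUDED = "excluded"

    @property
    def shared(self) -> bool:
        return self.value.startswith("shared")

    @property
    def recoded(self) -> bool:
        """True when the 0/1 allele meaning must be complemented."""
        return self in (MatchClass.SHARED_REFALT_SWAP, MatchClass.SHARED_SWAP_AND_FLIP)


@dataclass
class TargetRefAlignment:
    """Per-target-variant classification against a reference variant table."""

    classes: list[MatchClass]
    ref_index: np.ndarray  # reference site index per target variant (-1 if none)
    flip: np.ndarray  # bool per target variant: complement 0/1 meaning

    @property
    def shared_target_idx(self) -> np.ndarray:
        return np.flatnonzero([c.shared for c in self.classes])

    @property
    def shared_ref_idx(self) -> np.ndarray:
        return self.ref_index[self.shared_target_idx]

    @property
    def shared_flip(self) -> np.ndarray:
        return self.flip[self.shared_target_idx]

    def n_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.classes:
            out[c.value] = out.get(c.value, 0) + 1
        return out


def _is_snv(v: VariantRecord) -> bool:
    return (
        len(v.ref_allele) == 1
        and len(v.alt_allele) == 1
        and v.ref_allele in _COMPLEMENT
        and v.alt_allele in _COMPLEMENT
    )


def _strand_ambiguous(v: VariantRecord) -> bool:
    return _COMPLEMENT[v.ref_allele] == v.alt_allele


def reconcile_variants(
    target_variants: list[VariantRecord],
    reference_variants: list[VariantRecord],
    allow_refalt_swap: bool = False,
    allow_strand_flip: bool = False,
) -> TargetRefAlignment:
    """Classify each target variant against the reference by (chrom, pos).

    Exact REF/ALT agreement is ``shared``; reversed alleles are a ref/alt
    swap (recoded iff ``allow_refalt_swap``); complement-strand agreement is
    a strand flip (iff ``allow_strand_flip``); both transformations need
    both flags.  Strand-ambiguous A/T and C/G variants only ever match
    exactly or as a swap.  Positions absent from the reference are
    ``target_only``; duplicate positions with conflicting alleles are
    excluded with a warning.
    """
    by_pos: dict[tuple[str, int], list[int]] = {}
    for j, rv in enumerate(reference_variants):
        by_pos.setdefault((rv.chrom, rv.pos), []).append(j)

    n = len(target_variants)
    classes: list[MatchClass] = []
    ref_index = np.full(n, -1, dtype=np.int64)
    flip = np.zeros(n, dtype=bool)
    seen_ref: set[int] = set()

    for i, tv in enumerate(target_variants):
        cands = by_pos.get((tv.chrom, tv.pos), [])
        if not cands:
            classes.append(MatchClass.TARGET_ONLY)
            continue
        if not _is_snv(tv):
            classes.append(MatchClass.EXCLUDED)
            continue
        hits: list[tuple[int, MatchClass]] = []
        for j in cands:
            rv = reference_variants[j]
            if not _is_snv(rv):
                continue
            t = (tv.ref_allele, tv.alt_allele)
            r = (rv.ref_allele, rv.alt_allele)
            tc = (_COMPLEMENT[tv.ref_allele], _COMPLEMENT[tv.alt_allele])
            ambiguous = _strand_ambiguous(tv) or _strand_ambiguous(rv)
            if t == r:
                hits.append((j, MatchClass.SHARED))
            elif t == r[::-1]:
                hits.append((j, MatchClass.SHARED_REFALT_SWAP))
            elif not ambiguous and tc == r:
                hits.append((j, MatchClass.SHARED_STRAND_FLIP))
            elif not ambiguous and tc == r[::-1]:
                hits.append((j, MatchClass.SHARED_SWAP_AND_FLIP))
        if not hits:
            classes.append(MatchClass.EXCLUDED)
            log.warning(
                "variant %s:%d %s/%s matches position but not alleles; excluded",
                tv.chrom, tv.pos, tv.ref_allele, tv.alt_allele,
            )
            continue
        if len(hits) > 1:
            classes.append(MatchClass.EXCLUDED)
            log.warning(
                "variant %s:%d has conflicting duplicate matches; excluded",
                tv.chrom, tv.pos,
            )
            continue
        j, cls = hits[0]
        needs_swap = cls in (MatchClass.SHARED_REFALT_SWAP, MatchClass.SHARED_SWAP_AND_FLIP)
        needs_flip = cls in (MatchClass.SHARED_STRAND_FLIP, MatchClass.SHARED_SWAP_AND_FLIP)
        if (needs_swap and not allow_refalt_swap) or (needs_flip and not allow_strand_flip):
            classes.append(MatchClass.EXCLUDED)
            continue
        if j in seen_ref:
            classes.append(MatchClass.EXCLUDED)
            log.warning("reference site %d matched twice; later target excluded", j)
            continue
        seen_ref.add(j)
        classes.append(cls)
        ref_index[i] = j
        flip[i] = cls.recoded
    return TargetRefAlignment(classes, ref_index, flip)


@dataclass
class ParSlice:
    label: str
    records: list  # VariantRecord subset (or indices alongside)
    indices: np.ndarray
    ploidy: int  # ploidy for male samples in this slice


def split_par_regions(
    records: list[VariantRecord],
    par_definitions: dict[str, tuple[int, int]] | None = None,
    build: str = "GRCh38",
    x_names: tuple[str, ...] = ("X", "chrX"),
) -> list[ParSlice]:
    """Partition X-chromosome records into PAR (diploid) / non-PAR (haploid).

    Non-X chromosomes pass through unchanged as single diploid slices.  The
    concatenation of slice indices in output order equals the input order.
    """
    pars = par_definitions if par_definitions is not None else PAR_REGIONS[build]
    spans = sorted(pars.items(), key=lambda kv: kv[1][0])
    for (n1, (s1, e1)), (n2, (s2, e2)) in zip(spans, spans[1:]):
        if e1 > s2:
            raise ValueError(f"overlapping PAR definitions {n1} and {n2}")
    for name, (s, e) in spans:
        if s >= e:
            raise ValueError(f"empty/inverted PAR definition {name}")

    out: list[ParSlice] = []

    def flush(chrom: str, idx: list[int]) -> None:
        if not idx:
            return
        arr = np.asarray(idx)
        if chrom not in x_names:
            out.append(ParSlice(chrom, [records[i] for i in idx], arr, 2))
            return
        lab = np.empty(len(idx), dtype=object)
        for k, i in enumerate(idx):
            pos = records[i].pos
            lab[k] = next(
                (name for name, (s, e) in spans if s <= pos < e), "nonPAR"
            )
        # group maximal runs of equal label, preserving position order
        run_start = 0
        for k in range(1, len(idx) + 1):
            if k == len(idx) or lab[k] != lab[run_start]:
                sub = arr[run_start:k]
                name = lab[run_start]
                out.append(
                    ParSlice(
                        f"{chrom}_{name}",
                        [records[i] for i in sub],
                        sub,
                        2 if name != "nonPAR" else 1,
                    )
                )
                run_start = k

    cur_chrom: str | None = None
    cur: list[int] = []
    for i, r in enumerate(records):
        if r.chrom != cur_chrom:
            flush(cur_chrom, cur)
            cur_chrom, cur = r.chrom, []
        cur.append(i)
    flush(cur_chrom, cur)
    return out
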